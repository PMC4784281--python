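"""End-to-end pipeline driver: merge -> consensus -> map -> call (-> evaluate).

Two surfaces: :func:`process_reads` runs the read-level stages in memory and
returns every intermediate plus per-stage counters (the programmatic
workhorse), and :func:`run_pipeline` drives a whole configured run with file
outputs and a manifest.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import callvars, consensus, evaluate, io, merge, rotmap, simulate

logger = logging.getLogger("dropcirc")

SCHEMA_VERSION = 1

_STAGE_DEFAULTS = {
    "merge": {"min_overlap": 10, "max_mismatch_rate": 0.05, "min_mean_quality": 20.0},
    "consensus": {"min_period": 20, "max_mismatch_rate": 0.05},
    "rotmap": {"k": 12, "accept_threshold": None},
    "callvars": {"min_frequency": 0.02},
    "evaluate": {"edge_exclusion": 100, "lowess_window": 10, "lowess_frac": 0.05},
}


@dataclass
class PipelineConfig:
    """Validated stage parameter blocks; unknown keys are errors."""

    out_dir: str
    seed: int = 0
    criterion: str = "2X"
    simulate: dict | None = None  # SimConfig fields; None -> use `inputs`
    inputs: dict | None = None  # {"r1":..., "r2":..., "reference":...}
    merge: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    rotmap: dict = field(default_factory=dict)
    callvars: dict = field(default_factory=dict)
    evaluate: dict = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        if self.criterion not in ("1X", "2X"):
            raise ValueError("criterion must be '1X' or '2X'")
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of 'simulate' or 'inputs' must be given")
        for stage, defaults in _STAGE_DEFAULTS.items():
            block = dict(defaults)
            given = getattr(self, stage) or {}
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown keys in '{stage}' block: {sorted(unknown)}")
            block.update(given)
            setattr(self, stage, block)
        if self.simulate is not None:
            valid = set(simulate.SimConfig.__dataclass_fields__)
            unknown = set(self.simulate) - valid
            if unknown:
                raise ValueError(f"unknown keys in 'simulate' block: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = io.load_config(path)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        return cls(**raw)


def process_reads(
    reads,
    reference: str,
    merge_params: dict | None = None,
    consensus_params: dict | None = None,
    rotmap_params: dict | None = None,
    index: rotmap.KmerIndex | None = None,
):
    """Run merge -> consensus -> rotation mapping over read pairs in memory.

    ``reads`` is an iterable of (pair_id, r1_seq, r1_qual, r2_seq, r2_qual).
    Returns (mapped, intermediates, counters) where intermediates holds the
    merged reads, consensus sequences, and rejection records of every stage.
    """
    mp = {**_STAGE_DEFAULTS["merge"], **(merge_params or {})}
    cp = {**_STAGE_DEFAULTS["consensus"], **(consensus_params or {})}
    rp = {**_STAGE_DEFAULTS["rotmap"], **(rotmap_params or {})}
    if index is None:
        index = rotmap.build_index(reference, rp["k"])

    merged_reads, merge_rejects = [], []
    cs_list, cs_rejects = [], []
    mapped, map_rejects = [], []
    n_lowq = 0

    for pair_id, r1s, r1q, r2s, r2q in reads:
        if not merge.filter_read_pair((r1s, r1q), (r2s, r2q), mp["min_mean_quality"]):
            n_lowq += 1
            continue
        m = merge.merge_pair(
            (r1s, r1q), (r2s, r2q),
            min_overlap=mp["min_overlap"],
            max_mismatch_rate=mp["max_mismatch_rate"],
            pair_id=pair_id,
        )
        if isinstance(m, merge.MergeRejection):
            merge_rejects.append(m)
            continue
        merged_reads.append(m)

        p = consensus.find_period(
            m.sequence,
            max_mismatch_rate=cp["max_mismatch_rate"],
            min_period=cp["min_period"],
            read_id=pair_id,
        )
        if isinstance(p, consensus.PeriodRejection):
            cs_rejects.append(p)
            continue
        cs = consensus.call_consensus((m.sequence, m.qualities), p, read_id=pair_id)
        cs_list.append(cs)

        placed = rotmap.map_cs_seeded(cs, index, accept_threshold=rp["accept_threshold"])
        if isinstance(placed, rotmap.MapRejection):
            map_rejects.append(placed)
        else:
            mapped.append(placed)

    counters = {
        "pairs_in": n_lowq + len(merge_rejects) + len(merged_reads),
        "low_quality_pairs": n_lowq,
        "merged": len(merged_reads),
        "merge_rejected": len(merge_rejects),
        "cs_accepted": len(cs_list),
        "cs_rejected": len(cs_rejects),
        "mapped": len(mapped),
        "unmapped": len(map_rejects),
    }
    intermediates = {
        "merged": merged_reads,
        "merge_rejects": merge_rejects,
        "cs": cs_list,
        "cs_rejects": cs_rejects,
        "map_rejects": map_rejects,
    }
    return mapped, intermediates, counters


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig):
    """Execute the configured run, writing all intermediates plus a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed,
                      "complete": False, "stages": {}}
    manifest_path = out / "manifest.json"

    try:
        truth = None
        if config.simulate is not None:
            sim_cfg = simulate.SimConfig(**{**config.simulate, "seed": config.seed})
            reference = simulate.generate_reference(sim_cfg.genome_length, sim_cfg.seed)
            minor, variants = simulate.derive_strain(
                reference, sim_cfg.n_snps, sim_cfg.n_indels, sim_cfg.seed + 1
            )
            reads_bundle, truth = simulate.simulate_run(sim_cfg, reference, minor, variants)
            io.write_fasta(out / "reference.fasta", {"ref": reference})
            io.write_fastq_pair(out / "reads", reads_bundle)
            truth.molecules.to_csv(out / "truth_molecules.tsv", sep="\t", index=False)
            truth.damage.to_csv(out / "truth_damage.tsv", sep="\t", index=False)
            truth.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
            truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False)
            io.write_truth_vcf(out / "truth_variants.vcf", truth.variants, reference)
            reads_iter = list(
                zip(reads_bundle.ids, reads_bundle.r1_seq, reads_bundle.r1_qual,
                    reads_bundle.r2_seq, reads_bundle.r2_qual)
            )
            manifest["stages"]["simulate"] = {
                "molecules": len(truth.molecules), "read_pairs": len(reads_bundle)
            }
        else:
            reference = io.read_fasta(config.inputs["reference"])
            reference = next(iter(reference.values()))
            r1 = io.read_fastq(config.inputs["r1"])
            r2 = io.read_fastq(config.inputs["r2"])
            if len(r1) != len(r2):
                raise ValueError("R1/R2 record counts differ")
            reads_iter = [
                (a[0], a[1], a[2], b[1], b[2]) for a, b in zip(r1, r2)
            ]

        mapped, inter, counters = process_reads(
            reads_iter, reference,
            merge_params=config.merge,
            consensus_params=config.consensus,
            rotmap_params=config.rotmap,
        )
        logger.info("pipeline counters: %s", counters)
        manifest["stages"].update(counters)

        io.write_fastq(
            out / "merged.fastq",
            ((m.source_pair_id, m.sequence, m.qualities) for m in inter["merged"]),
        )
        with open(out / "merge_rejects.tsv", "w") as fh:
            fh.write("pair_id\treason\n")
            for r in inter["merge_rejects"]:
                fh.write(f"{r.source_pair_id}\t{r.reason}\n")
        io.write_cs_records(out / "cs.fasta", out / "cs.tsv", inter["cs"])
        io.write_mapped_tsv(out / "mapped.tsv", mapped)

        pileup = callvars.build_pileup(mapped, reference)
        calls = callvars.call_variants(
            pileup, criterion=config.criterion,
            min_frequency=config.callvars["min_frequency"],
        )
        io.write_vcf(out / "calls.vcf", calls)

        report = None
        if truth is not None and len(truth.variants):
            report = _evaluate_run(config, reference, pileup, calls, truth)
            with open(out / "report.json", "w") as fh:
                json.dump(report, fh, indent=2, sort_keys=True)

        manifest["stages"]["calls"] = len(calls)
        manifest["complete"] = True
        manifest["outputs"] = {
            p.name: _sha256(p) for p in sorted(out.iterdir())
            if p.name != "manifest.json" and p.is_file()
        }
        return report, manifest
    finally:
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _evaluate_run(config, reference, pileup, calls, truth) -> dict:
    ep = config.evaluate
    snps = truth.variants[truth.variants["vtype"] == "SNP"]
    golden = list(zip(snps["position"].astype(int), snps["alt"]))
    truth_positions = truth.variants["position"].astype(int).tolist()

    denom = callvars.assessed_bases(pileup)
    err = evaluate.error_rate(calls, truth_positions, {config.criterion: denom[config.criterion]})
    fpr, fnr, tp, fp, fn = evaluate.confusion(calls, golden)
    depth = evaluate.depth_vector(pileup, len(reference))
    cv, ratio_summary, _track = evaluate.depth_stats(
        depth, edge_exclusion=ep["edge_exclusion"],
        lowess_window=ep["lowess_window"], lowess_frac=ep["lowess_frac"],
    )
    site_depth = {pos: site.depth for pos, site in pileup.items()}
    fn_with_depth = [s for s in fn if s[0] in site_depth]
    classify = {}
    if fn_with_depth and depth.mean() > 0:
        classify = evaluate.classify_fn(fn_with_depth, site_depth, float(depth.mean()))
    fp_calls = [c for c in calls if (c.position, c.alt_base) in set(fp)]
    return {
        "error_rate": err,
        "fpr": fpr,
        "fnr": fnr,
        "n_tp": len(tp),
        "n_fp": len(fp),
        "n_fn": len(fn),
        "depth_cv_percent": cv,
        "depth_ratio_summary": ratio_summary,
        "fn_bias": {
            "SEQ_Bias": sum(1 for v in classify.values() if v == "SEQ_Bias"),
            "STR_Bias": sum(1 for v in classify.values() if v == "STR_Bias"),
        },
        "fp_frequency_histogram": evaluate.fp_frequency_histogram(fp_calls),
        "spectrum_fp": evaluate.spectrum(fp_calls),
    }
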