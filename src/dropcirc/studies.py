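"""Desk-scale simulation studies exercising the pipeline end to end.

Each study generates its own data with the simulator, runs the full
merge -> consensus -> map -> call chain, and measures one headline property
of the method: losslessness on clean data, the two-copy error-suppression
rate, seeded/exhaustive mapping agreement, junction-aware 2X specificity
against single-molecule artifacts, droplet-vs-bulk depth uniformity with the
FNR-vs-depth trade, and mixture-frequency recovery with the low-frequency
false-positive filter.  The same runners back the acceptance test suite and
the reproduction script, so the numbers they print are always recomputed.

Problem sizes are desk-scale analogs of the original design (kilobase
genomes, thousands to tens of thousands of read pairs) chosen so each study
finishes in minutes on one CPU while keeping every Monte-Carlo margin wide.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import callvars, consensus, evaluate, pipeline, rotmap, simulate
from ._seq import decode, revcomp, rotate

__all__ = [
    "identity_study",
    "error_suppression_study",
    "mapping_equivalence_study",
    "junction_specificity_study",
    "uniformity_cv_study",
    "subsample_fnr_study",
    "frequency_recovery_study",
]


def _simulate(cfg: simulate.SimConfig):
    ref = simulate.generate_reference(cfg.genome_length, cfg.seed)
    minor, variants = simulate.derive_strain(ref, cfg.n_snps, cfg.n_indels, cfg.seed + 1)
    reads, truth = simulate.simulate_run(cfg, ref, minor, variants)
    reads_iter = list(zip(reads.ids, reads.r1_seq, reads.r1_qual,
                          reads.r2_seq, reads.r2_qual))
    return ref, minor, variants, reads_iter, truth


def _golden_snps(variants):
    snps = variants[variants["vtype"] == "SNP"]
    return list(zip(snps["position"].astype(int), snps["alt"]))


def identity_study(seed: int) -> dict:
    """No-noise 1:1 run: the pipeline must be lossless and exact.

    10 kb genome, 50 truth SNPs, 5,000 read pairs, all error and damage rates
    zero.  Measures merge success, consensus recovery of the source fragment
    (up to rotation, masked only where coverage < 2), placement correctness
    (up to the circular-slide degeneracy), and FPR/FNR at sites with CS depth
    >= 5 under the 1X criterion.
    """
    cfg = simulate.SimConfig(
        genome_length=10_000, n_snps=50, n_indels=0, mixture_ratio=(1, 1),
        n_molecules=6_000, n_droplets=2_000, n_read_pairs=5_000,
        deamination_rate=0.0, polymerase_error_rate=0.0, seq_error_rate=0.0,
        seed=seed,
    )
    ref, minor, variants, reads_iter, truth = _simulate(cfg)
    mapped, inter, counters = pipeline.process_reads(reads_iter, ref)

    mol = truth.molecules.set_index("molecule_id")
    pair_mol = truth.pairs.set_index("pair_id")["molecule_id"]

    n_cs_ok = 0
    for cs in inter["cs"]:
        row = mol.loc[pair_mol[cs.source_read_id]]
        src = minor if row.strain == "minor" else ref
        frag = src[row.origin_start:row.origin_end]
        if row.strand == "-":
            frag = revcomp(frag)
        rotation_ok = len(cs.unit) == len(frag) and any(
            all(u in ("N", f) for u, f in zip(cs.unit, rotate(frag, r)))
            for r in range(len(frag))
        )
        mask_ok = all((u == "N") == (cc < 2)
                      for u, cc in zip(cs.unit, cs.copy_count))
        n_cs_ok += rotation_ok and mask_ok

    n_place_ok = sum(
        evaluate.placement_correct(
            m, mol.loc[pair_mol[m.cs_id], "origin_start"],
            mol.loc[pair_mol[m.cs_id], "strand"])
        for m in mapped
    )

    pileup = callvars.build_pileup(mapped, ref)
    calls = callvars.call_variants(pileup, "1X")
    golden = _golden_snps(variants)
    deep = {pos for pos, site in pileup.items() if site.depth >= 5}
    calls_deep = [c for c in calls if c.position in deep]
    golden_deep = [g for g in golden if g[0] in deep]
    fpr, fnr, tp, fp, fn = evaluate.confusion(calls_deep, golden_deep)

    return {
        "counters": counters,
        "merge_success": counters["merged"] / counters["pairs_in"],
        "cs_recovery": n_cs_ok / max(1, counters["cs_accepted"]),
        "placement_accuracy": n_place_ok / max(1, counters["mapped"]),
        "unmapped": counters["unmapped"],
        "fpr": fpr if fpr is not None else 0.0,
        "fnr": fnr if fnr is not None else 0.0,
        "n_golden_assessed": len(golden_deep),
    }


def error_suppression_study(seed: int, error_rate: float = 0.01,
                            period: int = 100, n_offsets: int = 1_000_000) -> dict:
    """Two-copy unanimity masking vs the analytic e^2/3 survival rate.

    Builds exact two-copy tandem reads, injects independent per-base
    sequencing errors at rate e, calls the consensus, and counts wrong bases
    that survive unmasked.  A wrong base survives only when both copies are
    hit by the same wrong base: probability e^2/3.
    """
    rng = np.random.default_rng(seed)
    n_reads = n_offsets // period
    frags = rng.integers(0, 4, size=(n_reads, period)).astype(np.uint8)
    merged = np.concatenate([frags, frags], axis=1)
    errs = rng.random(merged.shape) < error_rate
    shift = rng.integers(1, 4, size=merged.shape).astype(np.uint8)
    merged = np.where(errs, (merged + shift) % 4, merged).astype(np.uint8)

    survivors = 0
    masked = 0
    for i in range(n_reads):
        cs = consensus.call_consensus(decode(merged[i]), period)
        truth = decode(frags[i])
        for u, t in zip(cs.unit, truth):
            if u == "N":
                masked += 1
            elif u != t:
                survivors += 1
    total = n_reads * period
    p = error_rate**2 / 3
    sd = float(np.sqrt(total * p * (1 - p)))
    return {
        "n_offsets": total,
        "survivors": survivors,
        "masked": masked,
        "survival_rate": survivors / total,
        "expected_rate": p,
        "z": (survivors - total * p) / sd,
    }


def mapping_equivalence_study(seed: int, n_cs: int = 1000,
                              genome_length: int = 100_000,
                              max_mismatches: int = 3) -> dict:
    """Seeded mapping vs exhaustive rotation enumeration on random CSs."""
    ref = simulate.generate_reference(genome_length, seed)
    index = rotmap.build_index(ref, 12)
    rng = np.random.default_rng(seed + 1)
    n_agree = n_accepted = 0
    for _ in range(n_cs):
        p = int(rng.integers(80, 141))
        s = int(rng.integers(0, genome_length - p))
        frag = ref[s : s + p]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        unit = list(rotate(frag, int(rng.integers(0, p))))
        for pos in rng.choice(p, size=int(rng.integers(0, max_mismatches + 1)),
                              replace=False):
            unit[pos] = "ACGT"[("ACGT".index(unit[pos]) + int(rng.integers(1, 4))) % 4]
        unit = "".join(unit)
        ex = rotmap.map_cs(unit, ref)
        se = rotmap.map_cs_seeded(unit, index)
        ex_rej = isinstance(ex, rotmap.MapRejection)
        se_rej = isinstance(se, rotmap.MapRejection)
        if ex_rej or se_rej:
            n_agree += ex_rej == se_rej
            continue
        n_accepted += 1
        n_agree += (ex.start, ex.end, ex.strand, ex.junction_offset, ex.edit_cost) == (
            se.start, se.end, se.strand, se.junction_offset, se.edit_cost)
    return {"n_cs": n_cs, "n_accepted": n_accepted, "agreement": n_agree / n_cs}


def _molecules_behind(call, pileup, pair_mol):
    site = pileup[call.position]
    return {pair_mol[s.cs_id] for s in site.supporters if s.base == call.alt_base}


def junction_specificity_study(seed: int) -> dict:
    """2X specificity: single-molecule artifacts vs cross-molecule damage.

    Run A carries only per-copy polymerase and per-read sequencing errors —
    strictly single-molecule artifacts — and must yield no 2X call outside
    the truth set and no 2X call supported by a single molecule.  Run B adds
    pre-amplification cytosine deamination (rate 0.02 per C on the stored
    strand), which independently hits the same site in different molecules;
    its 2X false positives must be dominated (>= 90%) by C>T / G>A.
    """
    base = dict(
        genome_length=20_000, n_snps=30, n_indels=0, mixture_ratio=(1, 10),
        n_molecules=4_000, n_droplets=1_500, n_read_pairs=8_000,
        polymerase_error_rate=1e-4, seq_error_rate=0.005, seed=seed,
    )
    out = {}
    for label, deam in (("errors_only", 0.0), ("with_deamination", 0.02)):
        cfg = simulate.SimConfig(**base, deamination_rate=deam)
        ref, minor, variants, reads_iter, truth = _simulate(cfg)
        mapped, _, counters = pipeline.process_reads(reads_iter, ref)
        pileup = callvars.build_pileup(mapped, ref)
        calls = callvars.call_variants(pileup, "2X")
        pair_mol = truth.pairs.set_index("pair_id")["molecule_id"]
        truth_pos = set(variants["position"].astype(int))
        fp2 = [c for c in calls if c.position not in truth_pos]
        single_molecule = sum(
            len(_molecules_behind(c, pileup, pair_mol)) < 2 for c in calls
        )
        spec = evaluate.spectrum(fp2)
        n_fp = len(fp2)
        denom = callvars.assessed_bases(pileup)
        calls_1x = callvars.call_variants(pileup, "1X")
        err = {}
        err.update(evaluate.error_rate(calls_1x, truth_pos, {"1X": denom["1X"]}))
        err.update(evaluate.error_rate(calls, truth_pos, {"2X": denom["2X"]}))
        out[label] = {
            "n_2x_calls": len(calls),
            "n_2x_fp": n_fp,
            "single_molecule_2x": single_molecule,
            "ct_ga_fraction": (spec["C>T"] + spec["G>A"]) / n_fp if n_fp else None,
            "error_rate_1x": err["1X"],
            "error_rate_2x": err["2X"],
            "assessed_bases_1x": denom["1X"],
            "seq_error_rate": cfg.seq_error_rate,
        }
    return out


def _depth_cv_one(mode: str, seed: int) -> float:
    cfg = simulate.SimConfig(
        genome_length=10_000, n_snps=0, n_indels=0, mixture_ratio=(1, 10),
        n_molecules=2_000, n_droplets=700, n_read_pairs=2_500, mode=mode,
        deamination_rate=0.0, polymerase_error_rate=0.0, seq_error_rate=0.0,
        seed=seed,
    )
    ref, minor, variants, reads_iter, truth = _simulate(cfg)
    mapped, _, _ = pipeline.process_reads(reads_iter, ref)
    pileup = callvars.build_pileup(mapped, ref)
    depth = evaluate.depth_vector(pileup, cfg.genome_length)
    cv, _, _ = evaluate.depth_stats(depth, edge_exclusion=100)
    return cv


def uniformity_cv_study(seed: int, n_replicates: int = 5) -> dict:
    """Droplet-capped vs bulk competitive amplification depth CV, replicated.

    Equal total copy yield in both modes; one-sided Mann-Whitney test that
    bulk CV exceeds droplet CV.
    """
    seeds = [(seed * 1_000 + r) % 2**31 for r in range(n_replicates)]
    cv_droplet = [_depth_cv_one("droplet", s) for s in seeds]
    cv_bulk = [_depth_cv_one("bulk", s) for s in seeds]
    p = stats.mannwhitneyu(cv_bulk, cv_droplet, alternative="greater").pvalue
    return {
        "cv_droplet": cv_droplet,
        "cv_bulk": cv_bulk,
        "mean_cv_droplet": float(np.mean(cv_droplet)),
        "mean_cv_bulk": float(np.mean(cv_bulk)),
        "p_one_sided": float(p),
    }


SUBSAMPLE_TIERS = (6_000, 12_000, 24_000, 36_000, 48_000)


def subsample_fnr_study(seed: int) -> dict:
    """FNR vs consensus-sequence number over proportional subsampling tiers.

    One deep 1:10 run; the mapped CS set is subsampled to five tiers and the
    1X FNR against the truth SNPs is measured per tier.
    """
    cfg = simulate.SimConfig(
        genome_length=200_000, n_snps=600, n_indels=0, mixture_ratio=(1, 10),
        n_molecules=60_000, n_droplets=20_000, n_read_pairs=125_000,
        deamination_rate=0.0, polymerase_error_rate=0.0, seq_error_rate=0.0,
        seed=seed,
    )
    ref, minor, variants, reads_iter, truth = _simulate(cfg)
    mapped, _, counters = pipeline.process_reads(reads_iter, ref)
    golden = _golden_snps(variants)
    fnr_by_tier = {}
    for i, n in enumerate(SUBSAMPLE_TIERS):
        subset = callvars.subsample_cs(mapped, n, seed=seed + i)
        pileup = callvars.build_pileup(subset, ref)
        calls = callvars.call_variants(pileup, "1X")
        _, fnr, *_ = evaluate.confusion(calls, golden)
        fnr_by_tier[n] = fnr
    return {"total_mapped": counters["mapped"], "fnr_by_tier": fnr_by_tier}


def frequency_recovery_study(seed: int) -> dict:
    """Allele-frequency recovery on a 1:10 mixture plus the 0.02 filter.

    Measures the mean per-site frequency of truth-site calls against the
    exact mixture fraction (99% normal-theory interval on the between-site
    standard error), the fraction of sequencing-error false positives removed
    by the 0.02 frequency filter, and the absolute change in truth-site
    recall the filter causes.
    """
    cfg = simulate.SimConfig(
        genome_length=20_000, n_snps=100, n_indels=0, mixture_ratio=(1, 10),
        n_molecules=40_000, n_droplets=13_500, n_read_pairs=90_000,
        deamination_rate=0.0, polymerase_error_rate=0.0, seq_error_rate=0.01,
        seed=seed,
    )
    ref, minor, variants, reads_iter, truth = _simulate(cfg)
    mapped, _, _ = pipeline.process_reads(reads_iter, ref)
    pileup = callvars.build_pileup(mapped, ref)
    calls = callvars.call_variants(pileup, "1X", min_frequency=0.02)
    golden = set(_golden_snps(variants))
    truth_pos = {pos for pos, _ in golden}

    truth_freqs = [c.frequency for c in calls if (c.position, c.alt_base) in golden]
    mean_freq = float(np.mean(truth_freqs))
    se = float(np.std(truth_freqs, ddof=1) / np.sqrt(len(truth_freqs)))
    expected = cfg.minor_fraction

    fps = [c for c in calls if c.position not in truth_pos]
    removed = sum(not c.passed_frequency_filter for c in fps)
    recall_before = len({(c.position, c.alt_base) for c in calls
                         if (c.position, c.alt_base) in golden}) / len(golden)
    recall_after = len({(c.position, c.alt_base) for c in calls
                        if (c.position, c.alt_base) in golden
                        and c.passed_frequency_filter}) / len(golden)
    return {
        "n_truth_sites_called": len(truth_freqs),
        "mean_truth_frequency": mean_freq,
        "se_truth_frequency": se,
        "expected_frequency": expected,
        "ci99_halfwidth": 2.576 * se,
        "n_fp": len(fps),
        "fp_removed_by_filter": removed,
        "fp_removed_fraction": removed / len(fps) if fps else None,
        "recall_before_filter": recall_before,
        "recall_after_filter": recall_after,
        "recall_change": abs(recall_before - recall_after),
    }
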