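"""Droplet-partitioned rolling-circle amplification (RCA) read simulator.

Emulates the statistical structure of a droplet circle-sequencing experiment:
two bacterial strains mixed at a known ratio, single-strand fragments of
80-140 nt circularized and loaded into millions of picoliter droplets
(Poisson occupancy), amplified either with a per-droplet yield cap (droplet
mode) or with competitive heavy-tailed amplification in one tube (bulk mode),
damaged by cytosine deamination before amplification, copied with polymerase
errors, and finally sequenced as 2 x read_length paired-end reads sampled
from tandem-copy inserts.  Every stochastic event is recorded in ground-truth
tables so downstream calls can be audited molecule by molecule.

Randomness: one run seed; per-stage child streams are derived from it with
``numpy.random.SeedSequence(seed).spawn()`` in a fixed, documented order
(strains/origins, droplets, deamination, amplification, pair sampling,
sequencing errors), so each stage is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import decode, encode, phred_to_string

__all__ = [
    "SimConfig",
    "SimReads",
    "SimTruth",
    "generate_reference",
    "derive_strain",
    "minor_to_major_map",
    "simulate_run",
]

#: Phred score given to a simulated base that was read correctly.
QUAL_CORRECT = 37
#: Phred score given to a simulated sequencing-error base.
QUAL_ERROR = 20


@dataclass
class SimConfig:
    """Parameters of one simulated run.

    The defaults are a desk-scale analog of the study design: 80-140 nt
    single-strand fragments, a 1:10 minor:major strain mixture, mean droplet
    occupancy of 3 molecules (30,000 molecules in 10,000 droplets), 500-700 bp
    tandem-copy inserts sequenced as 2 x 150 bp pairs, and error rates in the
    middle of the ranges quoted for Illumina-class instruments (0.3% per
    sequenced base) and phi29 (1e-5 per copied base).
    """

    genome_length: int = 100_000
    n_snps: int = 345
    n_indels: int = 6
    mixture_ratio: tuple[int, int] = (1, 10)  # minor : major
    n_molecules: int = 30_000
    fragment_length_range: tuple[int, int] = (80, 140)
    n_droplets: int = 10_000
    mode: str = "droplet"  # droplet | bulk
    droplet_yield_copies: int = 300
    bulk_dispersion: float = 1.0
    deamination_rate: float = 0.001
    polymerase_error_rate: float = 1e-5
    seq_error_rate: float = 0.003
    read_length: int = 150
    insert_length_range: tuple[int, int] = (500, 700)
    n_read_pairs: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        fmin, fmax = self.fragment_length_range
        imin, imax = self.insert_length_range
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_molecules <= 0 or self.n_droplets <= 0 or self.n_read_pairs <= 0:
            raise ValueError("n_molecules, n_droplets, n_read_pairs must be positive")
        if not (0 < fmin <= fmax):
            raise ValueError("fragment_length_range must be a positive (min, max) pair")
        if fmax >= self.read_length:
            raise ValueError(
                "fragment max must be < read_length so every fragment is read "
                ">=2x per pair"
            )
        if imin < 2 * fmax:
            raise ValueError(
                "insert min must be >= 2x fragment max so the two mates read "
                "different tandem copies"
            )
        if imin > imax:
            raise ValueError("insert_length_range must be (min, max)")
        if self.mode not in ("droplet", "bulk"):
            raise ValueError("mode must be 'droplet' or 'bulk'")
        if self.droplet_yield_copies <= 0:
            raise ValueError("droplet_yield_copies must be positive")
        if self.bulk_dispersion <= 0:
            raise ValueError("bulk_dispersion must be positive")
        for name in ("deamination_rate", "polymerase_error_rate", "seq_error_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        minor, major = self.mixture_ratio
        if minor <= 0 or major <= 0:
            raise ValueError("mixture_ratio parts must be positive")

    @property
    def minor_fraction(self) -> float:
        minor, major = self.mixture_ratio
        return minor / (minor + major)


@dataclass
class SimReads:
    """Simulated paired-end reads (parallel lists; entry i is pair ``pair{i}``)."""

    ids: list[str]
    r1_seq: list[str]
    r1_qual: list[str]
    r2_seq: list[str]
    r2_qual: list[str]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class SimTruth:
    """Ground truth of a simulated run.

    molecules: one row per circularized molecule (strain, origin interval in
        reference coordinates, strand, droplet, copy yield, damage count).
    damage: one row per deamination event (molecule, fragment offset, and the
        induced reference-coordinate substitution).
    pairs: one row per emitted read pair (molecule, insert phase/length,
        injected polymerase/sequencing error counts).
    variants: the strain-distinguishing truth variants with their expected
        mixture frequency.
    """

    molecules: pd.DataFrame
    damage: pd.DataFrame
    pairs: pd.DataFrame
    variants: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def generate_reference(length: int, seed: int) -> str:
    """Uniform-random A/C/G/T reference of exactly ``length`` bases."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    return decode(rng.integers(0, 4, size=length).astype(np.uint8))


def derive_strain(
    reference: str, n_snps: int, n_indels: int, seed: int
) -> tuple[str, pd.DataFrame]:
    """Derive a minor strain by planting SNPs and 1-bp indels.

    Returns the mutated sequence and a truth table with 0-based reference
    coordinates.  Representation: SNP rows carry (ref base, alt base); DEL
    rows delete the base at ``position``; INS rows insert ``alt`` before
    ``position``.
    """
    if n_snps < 0 or n_indels < 0:
        raise ValueError("variant counts must be non-negative")
    n_total = n_snps + n_indels
    length = len(reference)
    if n_total > length // 10:
        raise ValueError("too many variants for this genome length")
    rng = np.random.default_rng(seed)
    positions = np.sort(rng.choice(length, size=n_total, replace=False))
    kinds = np.array(["SNP"] * n_snps + ["INDEL"] * n_indels)
    rng.shuffle(kinds)

    codes = encode(reference)
    rows = []
    pieces: list[str] = []
    prev = 0
    for pos, kind in zip(positions.tolist(), kinds.tolist()):
        pieces.append(reference[prev:pos])
        ref_base = reference[pos]
        if kind == "SNP":
            alt = "ACGT"[(int(codes[pos]) + int(rng.integers(1, 4))) % 4]
            pieces.append(alt)
            rows.append((pos, ref_base, alt, "SNP"))
        elif rng.random() < 0.5:  # deletion of the base at pos
            rows.append((pos, ref_base, "", "DEL"))
        else:  # insertion of one random base before pos
            ins = "ACGT"[int(rng.integers(0, 4))]
            pieces.append(ins + ref_base)
            rows.append((pos, "", ins, "INS"))
        prev = pos + 1
    pieces.append(reference[prev:])
    mutated = "".join(pieces)
    table = pd.DataFrame(rows, columns=["position", "ref", "alt", "vtype"])
    if table.empty:
        table = pd.DataFrame(columns=["position", "ref", "alt", "vtype"])
    return mutated, table


def minor_to_major_map(major_length: int, variants: pd.DataFrame) -> np.ndarray:
    """Map each minor-strain coordinate to its reference coordinate.

    Inserted bases are assigned the reference coordinate of the base they
    precede, so projected fragment intervals stay well formed.
    """
    out = np.empty(0, dtype=np.int64)
    chunks = []
    prev = 0
    indels = variants[variants["vtype"] != "SNP"].sort_values("position")
    for _, row in indels.iterrows():
        pos = int(row["position"])
        chunks.append(np.arange(prev, pos, dtype=np.int64))
        if row["vtype"] == "DEL":
            pass  # reference base pos has no minor coordinate
        else:  # INS: inserted base, then the anchor base itself
            chunks.append(np.array([pos, pos], dtype=np.int64))
        prev = pos + 1
    chunks.append(np.arange(prev, major_length, dtype=np.int64))
    out = np.concatenate(chunks) if chunks else out
    return out


def _largest_remainder_round(weights: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative weights to integers summing exactly to ``total``."""
    if weights.sum() == 0:
        raise ValueError("weights sum to zero")
    raw = weights / weights.sum() * total
    floors = np.floor(raw).astype(np.int64)
    short = total - int(floors.sum())
    if short > 0:
        order = np.argsort(-(raw - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


def _copy_numbers(
    cfg: SimConfig, droplet_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Per-molecule copy yields under the two amplification models.

    droplet mode: each occupied droplet's total yield is exactly
    ``droplet_yield_copies``, split evenly among its occupants (remainder to
    the lowest molecule indices — deterministic).  bulk mode: independent
    log-normal per-molecule factors with log-s.d. ``bulk_dispersion``,
    normalised to the same grand total, modelling competitive amplification.
    """
    n = len(droplet_ids)
    order = np.argsort(droplet_ids, kind="stable")
    sorted_ids = droplet_ids[order]
    uniq, starts, counts = np.unique(sorted_ids, return_index=True, return_counts=True)
    total_yield = cfg.droplet_yield_copies * len(uniq)

    copies = np.zeros(n, dtype=np.int64)
    if cfg.mode == "droplet":
        for s, c in zip(starts.tolist(), counts.tolist()):
            occupants = order[s : s + c]
            base, rem = divmod(cfg.droplet_yield_copies, c)
            share = np.full(c, base, dtype=np.int64)
            share[np.argsort(occupants, kind="stable")[:rem]] += 1
            copies[occupants] = share
    else:
        w = rng.lognormal(mean=0.0, sigma=cfg.bulk_dispersion, size=n)
        copies = _largest_remainder_round(w, total_yield)
    return copies


def _substitute(codes: np.ndarray, positions: np.ndarray, rng: np.random.Generator):
    """In place, replace bases at ``positions`` by a uniform different base."""
    if positions.size == 0:
        return
    shift = rng.integers(1, 4, size=positions.size).astype(np.uint8)
    codes[positions] = (codes[positions] + shift) % 4


def simulate_run(
    config: SimConfig,
    major_ref: str,
    minor_ref: str,
    truth_variants: pd.DataFrame,
) -> tuple[SimReads, SimTruth]:
    """Run the full generative model and return reads plus ground truth.

    Stages (each with its own child random stream):

    1. molecules drawn from major/minor in the mixture ratio, uniform origin
       interval and strand;
    2. uniform droplet assignment (Binomial occupancy ~ Poisson);
    3. deamination injected once per molecule BEFORE amplification, so all
       copies inherit it (C->T on the fragment's stored strand, visible as
       G->A on the reference for minus-strand fragments);
    4. amplification yields per molecule (droplet cap vs bulk log-normal);
    5. read pairs sample a molecule proportionally to its copy yield, take a
       random-phase tandem-copy insert, and inject polymerase errors
       independently per copied base (each insert base belongs to exactly one
       copy event);
    6. paired-end sequencing with independent per-base substitution errors.
    """
    cfg = config
    if len(minor_ref) == 0 or len(major_ref) == 0:
        raise ValueError("references must be non-empty")
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_mol = np.random.default_rng(streams[0])
    rng_drop = np.random.default_rng(streams[1])
    rng_deam = np.random.default_rng(streams[2])
    rng_amp = np.random.default_rng(streams[3])
    rng_pair = np.random.default_rng(streams[4])
    rng_seq = np.random.default_rng(streams[5])

    n = cfg.n_molecules
    fmin, fmax = cfg.fragment_length_range
    m2m = minor_to_major_map(len(major_ref), truth_variants)
    major_codes = encode(major_ref)
    minor_codes = encode(minor_ref)

    # --- stage 1: molecules -------------------------------------------------
    is_minor = rng_mol.random(n) < cfg.minor_fraction
    frag_len = rng_mol.integers(fmin, fmax + 1, size=n)
    strand_minus = rng_mol.random(n) < 0.5
    src_len = np.where(is_minor, len(minor_ref), len(major_ref))
    start = (rng_mol.random(n) * (src_len - frag_len)).astype(np.int64)

    # --- stage 2: droplets --------------------------------------------------
    droplet_ids = rng_drop.integers(0, cfg.n_droplets, size=n)

    # --- stage 3: deamination (pre-amplification) ---------------------------
    fragments: list[np.ndarray] = []
    damage_rows = []
    origin_start = np.empty(n, dtype=np.int64)
    origin_end = np.empty(n, dtype=np.int64)
    for i in range(n):
        fl = int(frag_len[i])
        s = int(start[i])
        if is_minor[i]:
            src = minor_codes[s : s + fl]
            o_start = int(m2m[s])
            o_end = int(m2m[s + fl - 1]) + 1
        else:
            src = major_codes[s : s + fl]
            o_start, o_end = s, s + fl
        origin_start[i], origin_end[i] = o_start, o_end
        if strand_minus[i]:
            frag = (3 - src[::-1]).astype(np.uint8)  # reverse complement
        else:
            frag = src.copy()
        if cfg.deamination_rate > 0:
            c_pos = np.flatnonzero(frag == 1)  # C on the stored strand
            if c_pos.size:
                hit = c_pos[rng_deam.random(c_pos.size) < cfg.deamination_rate]
                for off in hit.tolist():
                    frag[off] = 3  # C -> T on the stored strand
                    # source-strand coordinate of fragment offset `off`
                    src_off = fl - 1 - off if strand_minus[i] else off
                    if is_minor[i]:
                        ref_pos = int(m2m[s + src_off])
                    else:
                        ref_pos = s + src_off
                    if strand_minus[i]:
                        damage_rows.append((i, off, ref_pos, "G", "A"))
                    else:
                        damage_rows.append((i, off, ref_pos, "C", "T"))
        fragments.append(frag)

    # --- stage 4: amplification --------------------------------------------
    copies = _copy_numbers(cfg, droplet_ids, rng_amp)

    # --- stage 5 + 6: read pairs -------------------------------------------
    weights = copies / copies.sum()
    mol_of_pair = rng_pair.choice(n, size=cfg.n_read_pairs, p=weights)
    imin, imax = cfg.insert_length_range
    insert_len = rng_pair.integers(imin, imax + 1, size=cfg.n_read_pairs)
    rl = cfg.read_length

    ids, r1s, q1s, r2s, q2s = [], [], [], [], []
    pair_rows = []
    for j in range(cfg.n_read_pairs):
        mi = int(mol_of_pair[j])
        frag = fragments[mi]
        fl = frag.size
        il = int(insert_len[j])
        phase = int(rng_pair.integers(0, fl))
        reps = il // fl + 2
        insert = np.tile(frag, reps)[phase : phase + il]
        n_poly = 0
        if cfg.polymerase_error_rate > 0:
            poly_pos = np.flatnonzero(rng_pair.random(il) < cfg.polymerase_error_rate)
            _substitute(insert, poly_pos, rng_pair)
            n_poly = poly_pos.size
        r1 = insert[:rl].copy()
        r2 = (3 - insert[il - rl :][::-1]) % 4  # reverse complement mate

        q1 = np.full(rl, QUAL_CORRECT, dtype=np.int16)
        q2 = np.full(rl, QUAL_CORRECT, dtype=np.int16)
        n_err1 = n_err2 = 0
        if cfg.seq_error_rate > 0:
            e1 = np.flatnonzero(rng_seq.random(rl) < cfg.seq_error_rate)
            e2 = np.flatnonzero(rng_seq.random(rl) < cfg.seq_error_rate)
            _substitute(r1, e1, rng_seq)
            _substitute(r2, e2, rng_seq)
            q1[e1] = QUAL_ERROR
            q2[e2] = QUAL_ERROR
            n_err1, n_err2 = e1.size, e2.size

        ids.append(f"pair{j}")
        r1s.append(decode(r1.astype(np.uint8)))
        r2s.append(decode(r2.astype(np.uint8)))
        q1s.append(phred_to_string(q1))
        q2s.append(phred_to_string(q2))
        pair_rows.append((f"pair{j}", mi, il, phase, n_poly, n_err1, n_err2))

    molecules = pd.DataFrame(
        {
            "molecule_id": np.arange(n),
            "strain": np.where(is_minor, "minor", "major"),
            "origin_start": origin_start,
            "origin_end": origin_end,
            "strand": np.where(strand_minus, "-", "+"),
            "droplet_id": droplet_ids,
            "fragment_length": frag_len,
            "copies": copies,
        }
    )
    damage = pd.DataFrame(
        damage_rows,
        columns=["molecule_id", "offset", "ref_pos", "ref_from", "ref_to"],
    )
    pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "pair_id",
            "molecule_id",
            "insert_length",
            "phase",
            "n_polymerase_errors",
            "n_seq_errors_r1",
            "n_seq_errors_r2",
        ],
    )
    variants = truth_variants.copy()
    if len(variants):
        variants["expected_frequency"] = cfg.minor_fraction

    reads = SimReads(ids, r1s, q1s, r2s, q2s)
    truth = SimTruth(molecules, damage, pairs, variants, cfg)
    return reads, truth
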