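"""Rotation-insensitive placement of consensus sequences on the reference.

A consensus sequence (CS) is one full turn of a circle read at an arbitrary
phase, so its correct linear form is some rotation of the unit.  Every
rotation is a candidate on both strands; the placement with the fewest
mismatches + indels wins, which simultaneously recovers the circle's
junction (breakpoint): the rotation that restores the original fragment's
5' end.  Masked (N) positions are alignment-neutral — they match any base at
zero cost and zero reward.

Two equivalent search paths are provided: :func:`map_cs` scores every
rotation against the whole reference (the definitional, exhaustive form),
and :func:`map_cs_seeded` first collects candidate windows from exact k-mer
hits of the doubled unit (unit+unit contains every rotation as a substring)
and only aligns rotations inside those windows.  The seeded path is the one
the pipeline uses; its agreement with the exhaustive path is part of the
test suite.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import N_CODE, encode, revcomp, rotate

__all__ = [
    "MappedCS",
    "MapRejection",
    "KmerIndex",
    "build_index",
    "map_cs",
    "map_cs_seeded",
    "default_threshold",
]

# N matches anything at zero cost / zero reward
_N_EQUALITIES = [("N", b) for b in "ACGTN"]

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass
class MappedCS:
    """A consensus sequence placed on the reference.

    ``junction_offset`` is the rotation applied to the CS unit to obtain the
    linear fragment; ``linearized_sequence`` is that rotation (the fragment
    5'->3' on the reported strand).  ``aligned_query`` is the sequence that
    was aligned to the forward reference (the linearized sequence itself on
    '+', its reverse complement on '-').  The physical identity of the source
    circle — its breakpoint — is the fragment interval plus strand,
    ``junction_key``; CSs from the same circularized molecule share it
    regardless of the phase at which they were read.

    ``ambiguity_margin`` is the span of equal-cost slide placements at this
    locus (0 when the placement is unique).  A non-zero margin means the
    assignment of the outermost bases to reference columns is ambiguous —
    sliding the circle relocates boundary bases to the opposite end — so
    mismatches within the margin of either alignment end are not trustworthy
    allele evidence.
    """

    cs_id: str
    ref_id: str
    start: int  # 0-based
    end: int  # 0-based half-open reference end
    strand: str  # '+' | '-'
    junction_offset: int
    edit_cost: int
    alignment_ops: str  # run-length =/X/I/D string (I consumes query)
    linearized_sequence: str
    aligned_query: str
    ambiguity_margin: int = 0

    @property
    def junction_key(self) -> tuple:
        return (self.ref_id, self.start, self.end, self.strand)


@dataclass
class MapRejection:
    cs_id: str
    reason: str


def default_threshold(unmasked_length: int) -> int:
    """Default acceptance threshold: ceil(0.1 x unmasked CS length)."""
    return math.ceil(0.1 * unmasked_length)


def _unit_of(cs) -> tuple[str, str]:
    if isinstance(cs, str):
        return cs, ""
    return cs.unit, getattr(cs, "source_read_id", "")


def _queries(unit: str):
    """All (junction_offset, strand, query-aligned-to-forward-ref) triples."""
    period = len(unit)
    for r in range(period):
        rot = rotate(unit, r)
        yield r, "+", rot
        yield r, "-", revcomp(rot)


def _collect(query: str, target: str, k: int, target_offset: int, strand: str, r: int):
    res = edlib.align(query, target, mode="HW", task="locations", k=k,
                      additionalEqualities=_N_EQUALITIES)
    if res["editDistance"] < 0:
        return []
    cost = res["editDistance"]
    return [
        (cost, target_offset + loc[0], strand, r)
        for loc in res["locations"]
        if loc[0] is not None
    ]


def _gapless_cigar(mismatch_mask) -> str:
    """Run-length =/X string from a boolean mismatch mask."""
    ops = []
    run_op = None
    run_len = 0
    for mism in mismatch_mask:
        op = "X" if mism else "="
        if op == run_op:
            run_len += 1
        else:
            if run_op is not None:
                ops.append(f"{run_len}{run_op}")
            run_op, run_len = op, 1
    ops.append(f"{run_len}{run_op}")
    return "".join(ops)


def _try_gapless(unit, reference, strand, budget, start, margin):
    """Gapless re-placement near a gapped winning alignment.

    Unit-cost edit distance does not prefer substitutions over indels:
    adjacent strain differences can come back as an equal-cost
    delete+insert pair, and clustered boundary substitutions can even be
    strictly beaten by an indel-shifted placement — hiding or relocating
    allele evidence.  Since only substitutions are called, indels are
    effectively twice as expensive here: the best gapless placement of any
    rotation within the slide/indel neighborhood is adopted whenever its
    mismatch count is within ``budget`` (the gapped cost plus its indel
    columns).  Returns (start, end, cigar, junction_offset, margin,
    aligned_query, mismatches) or None.
    """
    period = len(unit)
    base = unit if strand == "+" else revcomp(unit)
    doubled = encode(base + base)
    # all rotations of the aligned-orientation sequence, as a (period, period) view
    rot_matrix = np.lib.stride_tricks.sliding_window_view(doubled, period)[:period]
    lo = max(0, start - budget - margin - 1)
    hi = min(len(reference) - period, start + budget + margin + 1)
    if hi < lo:
        return None
    ref_codes = encode(reference[lo : hi + period])
    best = None  # (ham, offset, junction_offset, rotation_index)
    hits: list[tuple[int, int]] = []  # (ham, offset)
    for o in range(lo, hi + 1):
        window = ref_codes[o - lo : o - lo + period]
        ham = (((rot_matrix != window) & (rot_matrix != N_CODE))).sum(axis=1)
        s = int(ham.argmin())
        h = int(ham[s])
        if h <= budget:
            hits.append((h, o))
            r = s if strand == "+" else (period - s) % period
            cand = (h, o, r, s)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        return None
    h, o, r, s = best
    query = base[s:] + base[:s]
    mism = (rot_matrix[s] != ref_codes[o - lo : o - lo + period]) & (
        rot_matrix[s] != N_CODE
    )
    tied = [off for hh, off in hits if hh == h]
    new_margin = (max(tied) - min(tied)) if len(tied) > 1 else 0
    return o, o + period, _gapless_cigar(mism), r, new_margin, query, h


def _finish(cs_id, ref_id, reference, unit, candidates, threshold):
    """Pick the minimal-cost placement, applying the ambiguity policy."""
    if not candidates:
        return MapRejection(cs_id, "no placement within threshold")
    best = min(c[0] for c in candidates)
    finalists = sorted(set(c for c in candidates if c[0] == best))
    strands = {c[2] for c in finalists}
    starts = [c[1] for c in finalists]
    period = len(unit)
    # distinct loci (different strand, or starts >= one period apart) tie -> ambiguous
    if len(strands) > 1 or (max(starts) - min(starts)) >= period:
        return MapRejection(cs_id, "ambiguous placement")
    # Same-locus ties are circular-slide degeneracies (the genome repeats the
    # fragment's first bases right after it).  Resolve by smallest start, then
    # smallest junction_offset: the start is a property of the locus, not of
    # the phase at which the circle was read, so all reads of one molecule
    # resolve to the same breakpoint interval.  The slide span is kept as the
    # placement's ambiguity margin.
    margin = max(starts) - min(starts)
    cost, start, strand, r = min(finalists, key=lambda c: (c[1], c[3]))
    rot = rotate(unit, r)
    query = rot if strand == "+" else revcomp(rot)
    lo = max(0, start - 2)
    hi = min(len(reference), start + len(query) + cost + 2)
    res = edlib.align(query, reference[lo:hi], mode="HW", task="path", k=cost,
                      additionalEqualities=_N_EQUALITIES)
    loc = res["locations"][0]
    final_start = lo + loc[0]
    final_end = lo + loc[1] + 1
    cigar = res["cigar"]
    if "I" in cigar or "D" in cigar:
        n_indels = sum(
            int(n) for n, op in _CIGAR_RE.findall(cigar) if op in ("I", "D")
        )
        budget = min(cost + n_indels, threshold)
        gapless = _try_gapless(unit, reference, strand, budget, final_start, margin)
        if gapless is not None:
            final_start, final_end, cigar, r, margin, query, cost = gapless
            rot = rotate(unit, r)
    return MappedCS(
        cs_id=cs_id,
        ref_id=ref_id,
        start=final_start,
        end=final_end,
        strand=strand,
        junction_offset=r,
        edit_cost=cost,
        alignment_ops=cigar,
        linearized_sequence=rot,
        aligned_query=query,
        ambiguity_margin=margin,
    )


def _check_cs(cs_id, unit):
    unmasked = sum(1 for b in unit if b != "N")
    if unmasked == 0:
        return None, MapRejection(cs_id, "fully masked")
    if unmasked < 0.5 * len(unit):
        return None, MapRejection(cs_id, "mostly masked")
    return unmasked, None


def map_cs(cs, reference: str, accept_threshold: int | None = None,
           ref_id: str = "ref") -> MappedCS | MapRejection:
    """Exhaustive rotation-by-rotation placement against the whole reference."""
    unit, cs_id = _unit_of(cs)
    unmasked, rej = _check_cs(cs_id, unit)
    if rej is not None:
        return rej
    k = accept_threshold if accept_threshold is not None else default_threshold(unmasked)
    candidates = []
    for r, strand, query in _queries(unit):
        candidates.extend(_collect(query, reference, k, 0, strand, r))
    return _finish(cs_id, ref_id, reference, unit, candidates, k)


class KmerIndex:
    """Exact k-mer -> forward reference positions; minus-strand lookups query
    the reverse complement of the k-mer."""

    def __init__(self, reference: str, k: int):
        if k < 8:
            raise ValueError("k must be >= 8")
        if len(reference) < k:
            raise ValueError("k larger than the reference")
        self.reference = reference
        self.k = k
        table: dict[str, list[int]] = {}
        for i in range(len(reference) - k + 1):
            table.setdefault(reference[i : i + k], []).append(i)
        self._table = {kmer: np.asarray(v, dtype=np.int64) for kmer, v in table.items()}

    def lookup(self, kmer: str) -> np.ndarray:
        return self._table.get(kmer, _EMPTY)


_EMPTY = np.empty(0, dtype=np.int64)


def build_index(reference: str, k: int = 12) -> KmerIndex:
    return KmerIndex(reference, k)


def _windows(positions: list[int], pad: int, ref_len: int) -> list[tuple[int, int]]:
    """Merge hit positions into padded, disjoint candidate windows."""
    if not positions:
        return []
    positions.sort()
    out = []
    lo = positions[0] - pad
    hi = positions[0] + pad
    for p in positions[1:]:
        if p - pad <= hi:
            hi = p + pad
        else:
            out.append((max(0, lo), min(ref_len, hi)))
            lo, hi = p - pad, p + pad
    out.append((max(0, lo), min(ref_len, hi)))
    return out


def map_cs_seeded(cs, index: KmerIndex, accept_threshold: int | None = None,
                  ref_id: str = "ref") -> MappedCS | MapRejection:
    """Seed-and-extend placement: k-mers of the doubled unit nominate
    reference windows, then every rotation is aligned inside each window."""
    unit, cs_id = _unit_of(cs)
    unmasked, rej = _check_cs(cs_id, unit)
    if rej is not None:
        return rej
    k_edit = accept_threshold if accept_threshold is not None else default_threshold(unmasked)
    reference = index.reference
    period = len(unit)
    doubled = unit + unit
    kk = index.k

    hits = {"+": [], "-": []}
    for q in range(len(doubled) - kk + 1):
        kmer = doubled[q : q + kk]
        if "N" in kmer:
            continue
        for p in index.lookup(kmer).tolist():
            hits["+"].append(p)
        for p in index.lookup(revcomp(kmer)).tolist():
            hits["-"].append(p)

    pad = 2 * period + kk
    candidates = []
    for strand in ("+", "-"):
        for lo, hi in _windows(hits[strand], pad, len(reference)):
            window = reference[lo:hi]
            for r in range(period):
                rot = rotate(unit, r)
                query = rot if strand == "+" else revcomp(rot)
                candidates.extend(_collect(query, window, k_edit, lo, strand, r))
    candidates = list(set(candidates))
    return _finish(cs_id, ref_id, reference, unit, candidates, k_edit)
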