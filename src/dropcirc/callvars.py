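"""Junction-aware pileup construction and 1X/2X variant calling.

Each mapped consensus sequence (CS) contributes its unmasked aligned bases
to a per-site pileup that remembers *which circle* the evidence came from:
every supporter carries the junction key (breakpoint interval + strand) of
its source molecule.  A variant is a "1X allele" when at least one CS
supports the alternate base, and a "2X allele" when at least two CSs with
*different* junction keys support it — evidence from two independently
circularized molecules, which suppresses both single-read errors and
single-molecule damage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .rotmap import MappedCS

__all__ = [
    "Supporter",
    "AlleleSupport",
    "VariantCall",
    "build_pileup",
    "call_variants",
    "subsample_cs",
    "assessed_bases",
    "distinct_junction_count",
]

DEFAULT_MIN_FREQUENCY = 0.02

#: Breakpoint intervals within this many bases of each other (same strand)
#: are counted as one junction.  When the genome repeats a fragment's
#: boundary bases, or a consensus masks them, the circle's linear placement
#: can slide by a base or two at equal cost, so reads of one molecule may
#: resolve to slightly different intervals; the slack keeps such reads from
#: masquerading as independent molecules.
JUNCTION_SLACK = 2

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


class Supporter(NamedTuple):
    cs_id: str
    junction_key: tuple
    base: str
    quality: int = 0


@dataclass
class AlleleSupport:
    """Per-site base support retaining the identity of each supporting CS."""

    ref_id: str
    position: int  # 0-based
    ref_base: str
    supporters: list[Supporter] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.supporters)

    def distinct_junctions(self) -> int:
        return distinct_junction_count(s.junction_key for s in self.supporters)


@dataclass
class VariantCall:
    ref_id: str
    position: int  # 0-based
    ref_base: str
    alt_base: str
    cs_support: int
    distinct_junction_support: int
    depth: int
    frequency: float
    criterion: str  # '1X' | '2X'
    passed_frequency_filter: bool


def distinct_junction_count(junction_keys, slack: int = JUNCTION_SLACK) -> int:
    """Number of distinct circularization junctions among supporter keys.

    Keys are (ref_id, start, end, strand) breakpoint intervals.  Same-strand
    intervals whose starts and ends both lie within ``slack`` bases chain into
    one junction (the circular-slide degeneracy); anything further apart is
    independent evidence.
    """
    keys = sorted(set(junction_keys), key=lambda k: (k[0], k[3], k[1], k[2]))
    clusters = 0
    prev = None
    for ref_id, start, end, strand in keys:
        if (
            prev is None
            or prev[0] != ref_id
            or prev[1] != strand
            or start - prev[2] > slack
            or abs(end - prev[3]) > slack
        ):
            clusters += 1
        prev = (ref_id, strand, start, end)
    return clusters


def build_pileup(mapped: list[MappedCS], reference: str) -> dict[int, AlleleSupport]:
    """Walk each CS alignment and deposit unmasked bases onto reference sites.

    CIGAR semantics: '=' / 'X' consume both query and reference, 'I' consumes
    query only, 'D' consumes reference only.  N query bases contribute
    nothing.  When a CS has equal-cost slide placements (a non-zero
    ``ambiguity_margin``), mismatches within the margin of either alignment
    end are rotation-ambiguous — sliding relocates boundary bases to the
    opposite end — and are excluded from allele evidence (matches are kept).
    Returns {position: AlleleSupport} for covered sites.
    """
    pileup: dict[int, AlleleSupport] = {}
    ref_len = len(reference)
    for m in mapped:
        pos = m.start
        qpos = 0
        query = m.aligned_query
        margin = getattr(m, "ambiguity_margin", 0)
        lo_edge = m.start + margin
        hi_edge = m.end - 1 - margin
        for length_s, op in _CIGAR_RE.findall(m.alignment_ops):
            length = int(length_s)
            if op in ("=", "X"):
                for i in range(length):
                    if pos + i >= ref_len:
                        raise ValueError(f"alignment of {m.cs_id} overflows the reference")
                    base = query[qpos + i]
                    if base == "N":
                        continue
                    if op == "X" and not (lo_edge <= pos + i <= hi_edge):
                        continue  # rotation-ambiguous boundary mismatch
                    site = pileup.get(pos + i)
                    if site is None:
                        site = AlleleSupport(m.ref_id, pos + i, reference[pos + i])
                        pileup[pos + i] = site
                    site.supporters.append(Supporter(m.cs_id, m.junction_key, base))
                pos += length
                qpos += length
            elif op == "I":
                qpos += length
            elif op == "D":
                pos += length
        if pos > ref_len:
            raise ValueError(f"alignment of {m.cs_id} overflows the reference")
    return pileup


def call_variants(
    pileup: dict[int, AlleleSupport],
    criterion: str = "2X",
    min_frequency: float = DEFAULT_MIN_FREQUENCY,
) -> list[VariantCall]:
    """Emit substitution calls under the 1X or 2X support criterion.

    1X: any site with >=1 non-reference supporter yields a call per alt base.
    2X: additionally requires >=2 supporters of that alt base with distinct
    junction keys (two different circularized molecules).  ``frequency`` is
    alt support / CS depth at the site; calls with frequency below
    ``min_frequency`` are flagged, not dropped.
    """
    if criterion not in ("1X", "2X"):
        raise ValueError("criterion must be '1X' or '2X'")
    if not (0.0 <= min_frequency <= 1.0):
        raise ValueError("min_frequency must be in [0, 1]")
    calls: list[VariantCall] = []
    for pos in sorted(pileup):
        site = pileup[pos]
        if site.ref_base == "N" or site.depth == 0:
            continue
        by_alt: dict[str, list[Supporter]] = {}
        for s in site.supporters:
            if s.base != site.ref_base and s.base != "N":
                by_alt.setdefault(s.base, []).append(s)
        for alt in sorted(by_alt):
            sup = by_alt[alt]
            dj = distinct_junction_count(s.junction_key for s in sup)
            if criterion == "2X" and dj < 2:
                continue
            freq = len(sup) / site.depth
            calls.append(
                VariantCall(
                    ref_id=site.ref_id,
                    position=pos,
                    ref_base=site.ref_base,
                    alt_base=alt,
                    cs_support=len(sup),
                    distinct_junction_support=dj,
                    depth=site.depth,
                    frequency=freq,
                    criterion=criterion,
                    passed_frequency_filter=freq >= min_frequency,
                )
            )
    return calls


def subsample_cs(mapped: list[MappedCS], n: int, seed: int) -> list[MappedCS]:
    """Uniform sample without replacement, canonicalized by (ref_id, start)."""
    if n > len(mapped):
        raise ValueError("cannot subsample more CSs than available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(mapped), size=n, replace=False)
    chosen = [mapped[i] for i in idx]
    chosen.sort(key=lambda m: (m.ref_id, m.start, m.cs_id))
    return chosen


def assessed_bases(pileup: dict[int, AlleleSupport]) -> dict[str, int]:
    """Per-criterion denominators for error-rate computation.

    1X: every piled (unmasked) consensus base.  2X: piled bases at sites
    where >=2 distinct junctions are present (only there could a 2X call
    arise).
    """
    total_1x = 0
    total_2x = 0
    for site in pileup.values():
        total_1x += site.depth
        if site.distinct_junctions() >= 2:
            total_2x += site.depth
    return {"1X": total_1x, "2X": total_2x}
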