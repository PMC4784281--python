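"""Evaluation statistics: error rate, substitution spectrum, depth
uniformity (ratio / CV / LOWESS), confusion vs a truth set, false-negative
bias classification and false-positive frequency spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "EvaluationReport",
    "error_rate",
    "spectrum",
    "depth_stats",
    "confusion",
    "classify_fn",
    "fp_frequency_histogram",
    "depth_vector",
    "placement_correct",
]

SUBSTITUTION_TYPES = [
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
]  # the 12 ordered reference-strand substitutions

#: FN sites at or below this fraction of the mean depth are attributed to
#: sequence-context amplification bias; above it, to strand bias.  The
#: anchor is a 30X cut at 80X mean, generalized as the fixed ratio 30/80.
SEQ_BIAS_DEPTH_FRACTION = 30.0 / 80.0


@dataclass
class EvaluationReport:
    error_rate_1x: float | None = None
    error_rate_2x: float | None = None
    spectrum: dict = field(default_factory=dict)
    depth_cv: float | None = None
    depth_ratio_summary: dict = field(default_factory=dict)
    lowess_track: pd.DataFrame | None = None
    fpr: float | None = None
    fnr: float | None = None
    fn_bias: dict = field(default_factory=dict)
    fp_frequency_histogram: dict = field(default_factory=dict)


def error_rate(calls, truth_positions, total_assessed_bases_by_criterion: dict) -> dict:
    """Per-criterion error rate: alt CS observations at non-truth sites over
    assessed consensus bases.  ``truth_positions`` must include every
    polymorphic position to exclude (SNP and indel loci).  A zero denominator
    yields None (absent), not 0.
    """
    truth = set(truth_positions)
    out: dict[str, float | None] = {}
    for criterion, denom in total_assessed_bases_by_criterion.items():
        num = sum(
            c.cs_support
            for c in calls
            if c.criterion == criterion and c.position not in truth
        )
        out[criterion] = (num / denom) if denom > 0 else None
    return out


def spectrum(records) -> dict[str, int]:
    """Counts of the 12 ordered reference-strand substitutions.

    ``records`` is an iterable of objects with ``ref_base``/``alt_base`` (or
    (ref, alt) pairs).  Complementary types are not collapsed.
    """
    counts = {key: 0 for key in SUBSTITUTION_TYPES}
    for rec in records:
        if hasattr(rec, "ref_base"):
            ref, alt = rec.ref_base, rec.alt_base
        else:
            ref, alt = rec
        if ref == alt:
            raise ValueError("substitution record with ref == alt")
        counts[f"{ref}>{alt}"] += 1
    return counts


def depth_vector(pileup, genome_length: int) -> np.ndarray:
    """CS depth per reference base from a pileup dict."""
    depth = np.zeros(genome_length, dtype=np.int64)
    for pos, site in pileup.items():
        depth[pos] = site.depth
    return depth


def depth_stats(
    per_base_depth,
    edge_exclusion: int = 100,
    lowess_window: int = 10,
    lowess_frac: float = 0.05,
):
    """Depth uniformity statistics.

    Excludes the first and last ``edge_exclusion`` bases, then reports:
    the depth CV (sample standard deviation / mean, in percent), the
    min/median/max of per-base depth over its mean, and a LOWESS smoothing of
    the natural-log depth ratio over non-overlapping ``lowess_window``-bp
    windows (windows with zero mean depth are dropped from the track).
    Returns (cv_percent, ratio_summary, lowess_track); CV is None when the
    retained depth is all zero.
    """
    depth = np.asarray(per_base_depth, dtype=float)
    if depth.size <= 2 * edge_exclusion:
        raise ValueError("depth vector shorter than twice the edge exclusion")
    if edge_exclusion > 0:
        depth = depth[edge_exclusion:-edge_exclusion]
    mean = depth.mean()
    if mean == 0:
        return None, {}, None
    cv = depth.std(ddof=1) / mean * 100.0
    ratio = depth / mean
    summary = {
        "min": float(ratio.min()),
        "median": float(np.median(ratio)),
        "max": float(ratio.max()),
    }
    n_win = depth.size // lowess_window
    win = depth[: n_win * lowess_window].reshape(n_win, lowess_window).mean(axis=1)
    mid = edge_exclusion + np.arange(n_win) * lowess_window + lowess_window / 2.0
    keep = win > 0
    track = None
    if keep.sum() >= 2:
        logratio = np.log(win[keep] / mean)
        frac = max(lowess_frac, min(1.0, 3.0 / keep.sum()))  # >=3 points per fit
        sm = _sm_lowess(logratio, mid[keep], frac=frac, return_sorted=True)
        track = pd.DataFrame({"midpoint": sm[:, 0], "log_ratio": sm[:, 1]})
    return float(cv), summary, track


def placement_correct(mapped, origin_start: int, strand: str) -> bool:
    """Is a mapped CS placed at its molecule's true locus?

    Correct up to the circular-slide degeneracy: when the genome repeats a
    fragment's boundary bases, the circle has several exact linear placements
    whose starts differ by the repeat length, and no read can tell them
    apart.  A placement is therefore correct when the strand matches and the
    start lies within one period of the true fragment start.
    """
    period = len(mapped.linearized_sequence)
    return mapped.strand == strand and abs(mapped.start - origin_start) < period


def confusion(calls, golden_truth):
    """Site+alt confusion vs a golden truth set.

    ``golden_truth``: iterable of (position, alt) pairs (or objects with
    .position/.alt).  FPR = FP/(FP+TP) — against called positives, the only
    reading compatible with reported FPRs near 1 on sparse truth sets.
    Returns (fpr, fnr, tp, fp, fn) where the last three are sorted site
    lists; fpr/fnr are None when their denominator is empty.
    """
    golden = set()
    for g in golden_truth:
        if hasattr(g, "position"):
            golden.add((g.position, g.alt))
        else:
            golden.add((g[0], g[1]))
    called = {(c.position, c.alt_base) for c in calls}
    tp = sorted(called & golden)
    fp = sorted(called - golden)
    fn = sorted(golden - called)
    fpr = len(fp) / (len(fp) + len(tp)) if (fp or tp) else None
    fnr = len(fn) / (len(tp) + len(fn)) if (tp or fn) else None
    return fpr, fnr, tp, fp, fn


def classify_fn(fn_sites, per_site_depth: dict, mean_depth: float) -> dict:
    """Label FN sites SEQ_Bias (low depth) or STR_Bias (adequate depth).

    The cut is ``SEQ_BIAS_DEPTH_FRACTION x mean_depth`` (30X at a mean of
    80X); a site at or below the cut is SEQ_Bias.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    threshold = SEQ_BIAS_DEPTH_FRACTION * mean_depth
    labels = {}
    for site in fn_sites:
        pos = site[0] if isinstance(site, tuple) else site
        if pos not in per_site_depth:
            raise ValueError(f"FN site {pos} has no depth record")
        labels[site] = "SEQ_Bias" if per_site_depth[pos] <= threshold else "STR_Bias"
    return labels


def fp_frequency_histogram(fp_calls) -> dict[str, int]:
    """FP mutation-frequency counts in [0,0.01), [0.01,0.02], (0.02,1].

    The 0.02 boundary belongs to the middle bin, matching a "<= 0.02"
    low-frequency classification.
    """
    bins = {"[0,0.01)": 0, "[0.01,0.02]": 0, "(0.02,1]": 0}
    for c in fp_calls:
        f = c.frequency if hasattr(c, "frequency") else float(c)
        if not (0 < f <= 1):
            raise ValueError(f"frequency {f} outside (0, 1]")
        if f < 0.01:
            bins["[0,0.01)"] += 1
        elif f <= 0.02:
            bins["[0.01,0.02]"] += 1
        else:
            bins["(0.02,1]"] += 1
    return bins
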