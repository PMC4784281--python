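"""Overlap-merge of a read pair into one longer tandem-copy read.

Read1 and the reverse complement of Read2 are merged by sequence overlap.
Because both mates read tandem copies of the same small circle, an overlap
exists even when the physical insert is far longer than the two reads
combined: the mates' phases on the circle line up modulo the period, and the
merged read is again a contiguous tandem copy of the circle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import N_CODE, decode, encode, revcomp_codes, string_to_phred

__all__ = ["MergedRead", "MergeRejection", "merge_pair", "filter_read_pair"]

DEFAULT_MIN_OVERLAP = 10
DEFAULT_MAX_MISMATCH_RATE = 0.05


@dataclass
class MergedRead:
    """A merged pair: Read1 + revcomp(Read2) collapsed over their overlap."""

    sequence: str
    qualities: np.ndarray  # per-base Phred, same length as sequence
    overlap_length: int
    source_pair_id: str = ""


@dataclass
class MergeRejection:
    source_pair_id: str
    reason: str


def _as_quals(quals, length: int) -> np.ndarray:
    if isinstance(quals, str):
        q = string_to_phred(quals)
    else:
        q = np.asarray(quals, dtype=np.int16)
    if q.size != length:
        raise ValueError("quality length does not match sequence length")
    return q


def merge_pair(
    read1: tuple[str, object],
    read2: tuple[str, object],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    pair_id: str = "",
) -> MergedRead | MergeRejection:
    """Merge (sequence, qualities) mates; return a rejection if none qualifies.

    Overlap lengths are scanned from ``min_overlap`` upward; the shortest
    overlap whose Hamming mismatch fraction is <= ``max_mismatch_rate`` wins.
    The mates of a tandem-copy insert overlap in phase (modulo the circle
    length), so every overlap in the matching phase class is equally true and
    the shortest one maximizes the merged read — and with it the number of
    circle offsets observed at least twice.  A spurious shorter overlap needs
    a chance suffix/prefix match of ``min_overlap`` bases (p ~ 4^-10 at the
    default).  Within the overlap, disagreeing bases take the higher-quality
    call; a quality tie is masked to N.
    """
    seq1, quals1 = read1
    seq2, quals2 = read2
    if not seq1 or not seq2:
        raise ValueError("reads must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not (0 <= max_mismatch_rate < 1):
        raise ValueError("max_mismatch_rate must be in [0, 1)")

    a = encode(seq1)
    q_a = _as_quals(quals1, a.size)
    b = revcomp_codes(encode(seq2))
    q_b = _as_quals(quals2, b.size)[::-1]

    max_ov = min(a.size, b.size)
    for ov in range(min_overlap, max_ov + 1):
        left = a[a.size - ov :]
        right = b[:ov]
        mism = left != right
        if mism.sum() / ov <= max_mismatch_rate:
            ql = q_a[a.size - ov :]
            qr = q_b[:ov]
            # agreement keeps the base at max quality; disagreement takes the
            # higher-quality call; a disagreeing quality tie is masked to N
            consensus = np.where(ql >= qr, left, right)
            cons_q = np.maximum(ql, qr)
            tie = mism & (ql == qr)
            consensus[tie] = N_CODE
            cons_q[tie] = 2
            merged = np.concatenate([a[: a.size - ov], consensus, b[ov:]])
            quals = np.concatenate([q_a[: a.size - ov], cons_q, q_b[ov:]])
            return MergedRead(decode(merged), quals.astype(np.int16), ov, pair_id)
    return MergeRejection(pair_id, "no qualifying overlap")


def filter_read_pair(read1, read2, min_mean_quality: float = 20.0) -> bool:
    """True iff both mates' mean Phred quality is >= the threshold (inclusive)."""
    for seq, quals in (read1, read2):
        q = _as_quals(quals, len(seq))
        if q.size == 0 or q.mean() < min_mean_quality:
            return False
    return True
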