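"""Tandem-period detection and masked consensus calling.

A merged read holds >=2 tandem copies of one circularized fragment.  The
smallest repeat unit (the period) is found by aligning the read against
itself at every candidate lag; the consensus sequence (CS) is then called
per circle offset, demanding unanimity among all observed copies.  Offsets
seen only once, or seen with disagreement, are hard-masked to N and carry no
evidence into variant calling — the error-correction core of the method:
with 2 copies and per-base error rate e, a wrong base survives unmasked only
when both copies are hit by the same wrong base (probability e^2/3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import N_CODE, decode, encode

__all__ = [
    "ConsensusSequence",
    "PeriodRejection",
    "find_period",
    "call_consensus",
]

DEFAULT_MIN_PERIOD = 20
DEFAULT_MAX_MISMATCH_RATE = 0.05
CONSENSUS_QUALITY_CAP = 60


@dataclass
class ConsensusSequence:
    """One repeat unit of the circle with per-offset evidence."""

    unit: str  # N at masked offsets
    period: int
    copy_count: np.ndarray  # copies observing each offset (non-N)
    agreement: np.ndarray  # per-offset bool: all observed copies agree
    consensus_quality: np.ndarray  # summed Phred of contributing copies, capped
    source_read_id: str = ""

    @property
    def masked_fraction(self) -> float:
        return (np.frombuffer(self.unit.encode(), dtype=np.uint8) == ord("N")).mean()


@dataclass
class PeriodRejection:
    source_read_id: str
    reason: str


def find_period(
    merged: str,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    min_period: int = DEFAULT_MIN_PERIOD,
    read_id: str = "",
) -> int | PeriodRejection:
    """Smallest lag p with self-alignment mismatch fraction <= the threshold.

    Positions where either compared base is N are not comparable and count
    in neither numerator nor denominator.  Returns a rejection when the read
    is shorter than two minimum periods or no lag qualifies.
    """
    codes = encode(merged)
    n = codes.size
    if n < 2 * min_period:
        return PeriodRejection(read_id, "too short")
    for p in range(min_period, n // 2 + 1):
        a = codes[:-p]
        b = codes[p:]
        comparable = (a != N_CODE) & (b != N_CODE)
        n_comp = int(comparable.sum())
        if n_comp == 0:
            continue
        mism = int(((a != b) & comparable).sum())
        if mism / n_comp <= max_mismatch_rate:
            return p
    return PeriodRejection(read_id, "no qualifying period")


def call_consensus(
    merged: tuple[str, object] | str,
    period: int,
    read_id: str = "",
) -> ConsensusSequence:
    """Unanimity consensus over the tandem copies of a merged read.

    ``merged`` is (sequence, per-base Phred array) or a bare sequence (then
    all qualities are taken as 30).  Per circle offset: the copies observing
    it are the merged bases at that offset plus every multiple of the period
    (N observations are missing data).  An offset observed once, or observed
    with any disagreement, is masked to N; a unanimous offset keeps its base
    with quality = sum of contributing Phred scores, capped at 60.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    if isinstance(merged, str):
        seq, quals = merged, np.full(len(merged), 30, dtype=np.int16)
    else:
        seq, quals = merged
        quals = np.asarray(quals, dtype=np.int16)
    codes = encode(seq)
    n = codes.size
    n_rows = -(-n // period)  # ceil
    padded = np.full(n_rows * period, N_CODE, dtype=np.uint8)
    padded[:n] = codes
    grid = padded.reshape(n_rows, period)
    qpad = np.zeros(n_rows * period, dtype=np.int64)
    qpad[:n] = quals
    qgrid = qpad.reshape(n_rows, period)

    observed = grid != N_CODE
    copy_count = observed.sum(axis=0)
    # unanimity: min == max over observed entries per column
    hi = np.where(observed, grid, 0).max(axis=0)
    lo = np.where(observed, grid, N_CODE).min(axis=0)
    agree = (hi == lo) & (copy_count > 0)

    unit = np.full(period, N_CODE, dtype=np.uint8)
    keep = agree & (copy_count >= 2)
    unit[keep] = hi[keep]
    quality = np.where(observed, qgrid, 0).sum(axis=0)
    quality = np.minimum(quality, CONSENSUS_QUALITY_CAP)
    quality[~keep] = 0

    return ConsensusSequence(
        unit=decode(unit),
        period=period,
        copy_count=copy_count.astype(np.int64),
        agreement=agree,
        consensus_quality=quality.astype(np.int64),
        source_read_id=read_id,
    )
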