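"""Shared low-level sequence helpers (encoding, reverse complement, rotation).

Bases are encoded as uint8: A=0, C=1, G=2, T=3, N=4.  N is the masked /
no-evidence symbol throughout the pipeline.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
N_CODE = 4

_ENCODE = np.full(256, N_CODE, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

# complement in code space: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a base string into the uint8 code space."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    """Reverse complement of a base string (N maps to N)."""
    return seq.translate(_COMP_TABLE)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def rotate(seq: str, offset: int) -> str:
    """Left rotation: rotate(s, j) = s[j:] + s[:j]."""
    if not seq:
        return seq
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def phred_to_string(quals) -> str:
    """Phred integer scores -> Phred+33 ASCII string."""
    arr = np.asarray(quals, dtype=np.uint8) + 33
    return arr.tobytes().decode()


def string_to_phred(qual_str: str) -> np.ndarray:
    """Phred+33 ASCII string -> integer scores; raises on unprintable junk."""
    arr = np.frombuffer(qual_str.encode(), dtype=np.uint8).astype(np.int16)
    arr = arr - 33
    if arr.size and (arr.min() < 0 or arr.max() > 60):
        raise ValueError("quality string is not valid Phred+33")
    return arr
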