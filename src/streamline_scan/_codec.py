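"""2-bit DNA encoding shared by the aligner and the simulators.

A/C/G/T map to 0..3, anything else (including N) to 4.  Code 4 never
matches any base, so ambiguous positions behave as guaranteed mismatches
in alignments and are excluded from k-mer seeding.
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space; code 4 (N) stays 4."""
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer integers for every window, plus a validity mask.

    Windows containing any non-ACGT base are flagged invalid; their packed
    value is meaningless and must not be used.  k must be <= 31 so the
    packed value fits an int64.
    """
    n = codes.shape[0]
    if not (1 <= k <= 31):
        raise ValueError(f"k must be in [1, 31], got {k}")
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    c = codes.astype(np.int64)
    m = n - k + 1
    packed = np.zeros(m, dtype=np.int64)
    for j in range(k):
        packed = (packed << 2) | (c[j : j + m] & 3)
    bad = (codes >= 4).astype(np.int64)
    if bad.any():
        cs = np.concatenate([[0], np.cumsum(bad)])
        valid = (cs[k:] - cs[:-k]) == 0
    else:
        valid = np.ones(m, dtype=bool)
    return packed, valid
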