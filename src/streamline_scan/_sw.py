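"""Banded affine-gap Smith-Waterman kernel (numba-compiled).

The band is defined around a seed diagonal d0: cell (i, j) is inside the
band iff |(j - i) - d0| <= bw.  Scoring is match/mismatch with affine
gaps where a gap of length L costs open + (L - 1) * extend.  Traceback
recovers matches, total alignment columns (gap columns included) and the
query/subject spans of the best local alignment.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(1 << 28)


@njit(cache=True, nogil=True)
def banded_sw(q, s, d0, bw, match, mismatch, gap_open, gap_ext):  # pragma: no cover
    m = q.shape[0]
    n = s.shape[0]
    W = 2 * bw + 1
    H = np.full((m + 1, W), NEG, np.int32)
    E = np.full((m + 1, W), NEG, np.int32)
    F = np.full((m + 1, W), NEG, np.int32)
    PH = np.zeros((m + 1, W), np.uint8)  # 0 stop, 1 diag, 2 from E, 3 from F
    PE = np.zeros((m + 1, W), np.uint8)  # 1 opened from H, 0 extended
    PF = np.zeros((m + 1, W), np.uint8)

    for b in range(W):
        j = 0 + d0 + b - bw
        if 0 <= j <= n:
            H[0, b] = 0

    best = 0
    bi = -1
    bb = -1
    for i in range(1, m + 1):
        qi = q[i - 1]
        for b in range(W):
            j = i + d0 + b - bw
            if j < 1 or j > n:
                continue
            # E: gap consuming subject, predecessor (i, j-1) -> band b-1
            e = NEG
            pe = np.uint8(0)
            if b - 1 >= 0:
                ho = H[i, b - 1]
                if ho > NEG // 2 and ho + gap_open > e:
                    e = ho + gap_open
                    pe = np.uint8(1)
                eo = E[i, b - 1]
                if eo > NEG // 2 and eo + gap_ext > e:
                    e = eo + gap_ext
                    pe = np.uint8(0)
            E[i, b] = e
            PE[i, b] = pe
            # F: gap consuming query, predecessor (i-1, j) -> band b+1
            f = NEG
            pf = np.uint8(0)
            if b + 1 < W:
                ho = H[i - 1, b + 1]
                if ho > NEG // 2 and ho + gap_open > f:
                    f = ho + gap_open
                    pf = np.uint8(1)
                fo = F[i - 1, b + 1]
                if fo > NEG // 2 and fo + gap_ext > f:
                    f = fo + gap_ext
                    pf = np.uint8(0)
            F[i, b] = f
            PF[i, b] = pf
            # H
            sj = s[j - 1]
            sub = match if (qi == sj and qi < 4) else mismatch
            h = 0
            ph = np.uint8(0)
            dh = H[i - 1, b]
            if dh > NEG // 2 and dh + sub > h:
                h = dh + sub
                ph = np.uint8(1)
            if e > h:
                h = e
                ph = np.uint8(2)
            if f > h:
                h = f
                ph = np.uint8(3)
            H[i, b] = h
            PH[i, b] = ph
            if h > best:
                best = h
                bi = i
                bb = b

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback
    i = bi
    b = bb
    state = 0  # 0=H, 1=E, 2=F
    matches = 0
    columns = 0
    while True:
        if state == 0:
            ph = PH[i, b]
            if ph == 0:
                break
            if ph == 1:
                j = i + d0 + b - bw
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    matches += 1
                columns += 1
                i -= 1
            elif ph == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            pe = PE[i, b]
            b -= 1
            state = 0 if pe == 1 else 1
        else:
            columns += 1
            pf = PF[i, b]
            i -= 1
            b += 1
            state = 0 if pf == 1 else 2

    q_start = i
    s_start = i + d0 + b - bw
    q_end = bi
    s_end = bi + d0 + bb - bw
    return best, matches, columns, q_start, q_end, s_start, s_end
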