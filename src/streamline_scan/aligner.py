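"""Seed-and-extend local nucleotide alignment with percent-identity reporting.

This is the workhorse behind both fragment recruitment and fragment-based
ANI: exact k-mer seeds are located on both strands of an indexed subject,
clustered per diagonal band, and the best cluster(s) are extended with a
banded affine-gap Smith-Waterman.  Only the single best hit per query is
retained, and percent identity counts gap columns in the denominator
(matches / alignment columns x 100), matching the identity BLASTN reports.

Scoring: match +1, mismatch -2, gap open -5, gap extend -2 (a gap of
length L costs -5 - 2(L-1)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._codec import encode, kmer_codes, revcomp_codes
from ._sw import banded_sw

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -2, -5, -2

#: default seed length for read recruitment (sensitive at >= 95% identity)
RECRUIT_K = 13
#: default seed length for ANI fragments (sensitive down to the 70-80% regime)
ANI_K = 11


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment of one query against an indexed subject."""

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    matches: int
    columns: int
    score: int

    @property
    def identity(self) -> float:
        """Percent identity: matches / alignment columns x 100."""
        return 100.0 * self.matches / self.columns

    @property
    def aligned_length(self) -> int:
        return self.columns

    def to_tab(self) -> str:
        """Tab-separated line loosely mimicking BLAST outfmt 6 columns."""
        mismatches = self.columns - self.matches
        return "\t".join(
            str(x)
            for x in (
                self.query_id, self.subject_id, f"{self.identity:.2f}",
                self.columns, mismatches, self.strand,
                self.q_start + 1, self.q_end, self.s_start + 1, self.s_end,
                self.score,
            )
        )


class SeedIndex:
    """Exact k-mer position index over a subject and its reverse complement.

    Positions are always reported on the forward strand; reverse-strand
    occurrences are resolved by looking up the reverse complement of the
    query k-mer, which is equivalent to indexing both strands.
    """

    def __init__(self, subject: str | np.ndarray, k: int = RECRUIT_K,
                 subject_id: str = "subject", max_seed_occ: int = 128):
        if not (8 <= k <= 31):
            raise ValueError(f"k must be in [8, 31], got {k}")
        codes = encode(subject) if isinstance(subject, str) else np.asarray(subject)
        if codes.size == 0:
            raise ValueError("cannot index an empty subject")
        self.k = k
        self.subject_id = subject_id
        self.codes = codes.astype(np.uint8)
        self.length = int(codes.size)
        self.max_seed_occ = max_seed_occ
        kc, valid = kmer_codes(self.codes, k)
        pos = np.flatnonzero(valid)
        kc = kc[pos]
        order = np.argsort(kc, kind="stable")
        self._sorted = kc[order]
        self._pos = pos[order].astype(np.int64)

    def positions(self, kmer: str, strand: str = "+") -> np.ndarray:
        """Forward-strand start positions of ``kmer`` (or of its reverse
        complement, for strand '-')."""
        if len(kmer) != self.k:
            raise ValueError(f"kmer length {len(kmer)} != k={self.k}")
        qc = encode(kmer)
        if strand == "-":
            qc = revcomp_codes(qc)
        kc, valid = kmer_codes(qc, self.k)
        if not valid[0]:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._sorted, kc[0], "left")
        hi = np.searchsorted(self._sorted, kc[0], "right")
        return np.sort(self._pos[lo:hi])

    def _match_seeds(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (query offset, subject position) exact seed matches."""
        kc, valid = kmer_codes(query_codes, self.k)
        qoff = np.flatnonzero(valid)
        if qoff.size == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        codes = kc[qoff]
        lo = np.searchsorted(self._sorted, codes, "left")
        hi = np.searchsorted(self._sorted, codes, "right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= self.max_seed_occ)
        if not keep.any():
            return np.empty(0, np.int64), np.empty(0, np.int64)
        qsel = qoff[keep]
        lo = lo[keep]
        hi = hi[keep]
        qpos = np.repeat(qsel, hi - lo)
        spos = np.concatenate([self._pos[a:b] for a, b in zip(lo, hi)])
        return qpos, spos


def _diagonal_clusters(diag: np.ndarray, band: int, max_clusters: int) -> list[np.ndarray]:
    """Indices of the densest diagonal windows of width ``band``.

    Returns up to ``max_clusters`` non-overlapping seed subsets, densest
    first; ties go to the lower diagonal (= lower subject start).
    """
    order = np.argsort(diag, kind="stable")
    d = diag[order]
    n = d.size
    hi = np.searchsorted(d, d + band, "right")
    support = hi - np.arange(n)
    clusters: list[np.ndarray] = []
    used = np.zeros(n, dtype=bool)
    for _ in range(max_clusters):
        avail = np.flatnonzero(~used)
        if avail.size == 0:
            break
        best = avail[np.argmax(support[avail])]
        if support[best] <= 0:
            break
        sel = np.arange(best, hi[best])
        sel = sel[~used[sel]]
        if sel.size == 0:
            break
        clusters.append(order[sel])
        lo_d, hi_d = d[best] - band, d[best] + 2 * band
        used |= (d >= lo_d) & (d <= hi_d)
        # support counts include used seeds; acceptable, clusters are disjoint
    return clusters


def _extend_cluster(query_codes, index, qpos, spos, band):
    """Banded DP around one seed cluster; returns raw kernel output."""
    diag = spos - qpos
    d_lo = int(diag.min())
    d_hi = int(diag.max())
    m = query_codes.size
    n = index.length
    pad = band + 4
    ws = max(0, d_lo - pad)
    we = min(n, d_hi + m + pad)
    d0 = (d_lo + d_hi) // 2 - ws
    eff_bw = band + (d_hi - d_lo + 1) // 2
    sub = np.ascontiguousarray(index.codes[ws:we])
    score, matches, columns, qs, qe, ss, se = banded_sw(
        query_codes, sub, d0, eff_bw, MATCH, MISMATCH, GAP_OPEN, GAP_EXT
    )
    if score <= 0:
        return None
    return score, matches, columns, qs, qe, ws + ss, ws + se


def best_local_hit(
    query: str,
    index: SeedIndex,
    min_identity: float = 0.0,
    min_aln_len: int = 0,
    band: int = 16,
    max_clusters: int = 2,
    query_id: str = "query",
) -> Optional[AlignmentHit]:
    """Best-scoring local hit of ``query`` meeting both thresholds, or None.

    Both strands are searched.  Ties are broken by lower subject start,
    then forward strand first.  ``min_aln_len`` is a bound on alignment
    columns (gap columns included).
    """
    qc_fwd = encode(query) if isinstance(query, str) else np.asarray(query, dtype=np.uint8)
    m = qc_fwd.size
    if m < index.k:
        raise ValueError(f"query length {m} < k={index.k}")
    candidates: list[tuple[tuple, AlignmentHit]] = []
    for strand, qc in (("+", qc_fwd), ("-", revcomp_codes(qc_fwd))):
        qpos, spos = index._match_seeds(qc)
        if qpos.size == 0:
            continue
        diag = spos - qpos
        for sel in _diagonal_clusters(diag, band, max_clusters):
            res = _extend_cluster(qc, index, qpos[sel], spos[sel], band)
            if res is None:
                continue
            score, matches, columns, qs, qe, ss, se = res
            if strand == "-":
                qs, qe = m - qe, m - qs
            hit = AlignmentHit(
                query_id, index.subject_id, int(qs), int(qe), int(ss), int(se),
                strand, int(matches), int(columns), int(score),
            )
            if hit.identity >= min_identity - 1e-9 and columns >= min_aln_len:
                candidates.append(((-hit.score, hit.s_start, strand == "-"), hit))
    if not candidates:
        return None
    return min(candidates, key=lambda t: t[0])[1]
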