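"""Metagenomic fragment recruitment and genomic-island calling.

Recruitment aligns every read of a database against a reference genome,
keeps at most one (best) hit per read that passes an identity/length
filter, and summarizes the result as (i) a per-position coverage track,
(ii) a normalized recruitment value comparable across genomes and read
databases, and (iii) the hit list itself.  Two filter modes mirror the
two published cut-offs:

* ``abs_len``  — identity >= 95% over >= 50 aligned bp (genome-abundance
  comparisons);
* ``frac_len`` — identity >= 95% over >= 50% of the read length
  (identity-vs-position plots and island detection).

Normalized recruitment = kept hits / (genome Mbp x database Mbp), where
the database size is the total read bases.  Genomic ("metagenomic")
islands are intervals whose windowed coverage falls far below the
genome-wide median — the signature of gene content that varies among
co-occurring lineages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .aligner import RECRUIT_K, AlignmentHit, SeedIndex, best_local_hit
from .io_formats import AnnotatedGenome, ReadSet

MIN_IDENTITY = 95.0
MIN_ALN_LEN = 50


@dataclass
class RecruitmentProfile:
    """Per-read best hits, coverage and normalized recruitment for one genome."""

    genome_id: str
    genome_length: int
    database_bases: int
    mode: str
    hits: list[AlignmentHit] = field(default_factory=list, repr=False)
    hit_weights: list[float] = field(default_factory=list, repr=False)
    coverage: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.coverage is None:
            self.coverage = np.zeros(self.genome_length, dtype=np.int64)

    def add_hit(self, hit: AlignmentHit, weight: float = 1.0) -> None:
        self.hits.append(hit)
        self.hit_weights.append(weight)
        self.coverage[hit.s_start : hit.s_end] += 1

    @property
    def kept_count(self) -> float:
        """Recruited read count (fractional under multi-genome ties)."""
        return float(sum(self.hit_weights))

    @property
    def normalized_recruitment(self) -> float:
        """Kept hits per Mbp of genome per Mbp of read database."""
        genome_mbp = self.genome_length / 1e6
        db_mbp = self.database_bases / 1e6
        if genome_mbp == 0 or db_mbp == 0:
            return 0.0
        return self.kept_count / (genome_mbp * db_mbp)


@dataclass(frozen=True)
class IslandCall:
    """A genome interval with depressed recruitment (0-based half-open)."""

    start: int
    end: int
    coverage_ratio: float
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _min_columns(mode: str, read_len: int, min_len: int) -> float:
    if mode == "abs_len":
        return min_len
    if mode == "frac_len":
        return (min_len / 100.0) * read_len if min_len > 1 else min_len * read_len
    raise ValueError(f"unknown recruitment mode {mode!r}")


def recruit(
    reads: ReadSet,
    genome: AnnotatedGenome,
    mode: str = "abs_len",
    min_identity: float = MIN_IDENTITY,
    min_len: float = MIN_ALN_LEN,
    k: int = RECRUIT_K,
    band: int = 16,
    index: Optional[SeedIndex] = None,
) -> RecruitmentProfile:
    """Recruit a read database against one genome.

    ``min_len`` is aligned bp for ``abs_len``; for ``frac_len`` it is a
    percentage of the read length (50 means half the read).
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    if index is None:
        index = SeedIndex(genome.sequence, k=k, subject_id=genome.id)
    profile = RecruitmentProfile(genome.id, len(genome), reads.total_bases, mode)
    for rid, seq in reads.reads:
        if len(seq) < index.k:
            continue
        min_cols = _min_columns(mode, len(seq), min_len)
        hit = best_local_hit(
            seq, index, min_identity=min_identity,
            min_aln_len=0, band=band, query_id=rid,
        )
        if hit is None:
            continue
        if hit.identity >= min_identity - 1e-9 and hit.columns >= min_cols - 1e-9:
            profile.add_hit(hit)
    return profile


def recruit_community(
    reads: ReadSet,
    genomes: Sequence[AnnotatedGenome],
    mode: str = "abs_len",
    min_identity: float = MIN_IDENTITY,
    min_len: float = MIN_ALN_LEN,
    k: int = RECRUIT_K,
    band: int = 16,
) -> dict[str, RecruitmentProfile]:
    """Recruit one read database against several genomes at once.

    Each read is assigned to the genome where it hits with the highest
    identity; exact identity ties are counted fractionally (1/n to each
    tied genome) so abundances are not inflated.
    """
    if len(reads) == 0:
        raise ValueError("empty read set")
    indexes = [SeedIndex(g.sequence, k=k, subject_id=g.id) for g in genomes]
    profiles = {
        g.id: RecruitmentProfile(g.id, len(g), reads.total_bases, mode)
        for g in genomes
    }
    for rid, seq in reads.reads:
        if len(seq) < k:
            continue
        min_cols = _min_columns(mode, len(seq), min_len)
        passing: list[tuple[str, AlignmentHit]] = []
        for g, idx in zip(genomes, indexes):
            hit = best_local_hit(seq, idx, min_identity=min_identity,
                                 min_aln_len=0, band=band, query_id=rid)
            if hit is None:
                continue
            if hit.identity >= min_identity - 1e-9 and hit.columns >= min_cols - 1e-9:
                passing.append((g.id, hit))
        if not passing:
            continue
        best_ident = max(h.identity for _, h in passing)
        tied = [(gid, h) for gid, h in passing if h.identity >= best_ident - 1e-12]
        w = 1.0 / len(tied)
        for gid, h in tied:
            profiles[gid].add_hit(h, weight=w)
    return profiles


def _window_means(coverage: np.ndarray, window: int, step: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    n = coverage.size
    if n <= window:
        return np.array([0]), np.array([coverage.mean()])
    starts = np.arange(0, n - window + 1, step)
    if starts[-1] != n - window:
        starts = np.append(starts, n - window)
    cs = np.concatenate([[0], np.cumsum(coverage)])
    means = (cs[starts + window] - cs[starts]) / window
    return starts, means


def call_islands(
    profile: RecruitmentProfile,
    window: int = 10_000,
    step: int = 1_000,
    ratio_threshold: float = 0.2,
    merge_gap: int = 2_000,
    min_len: int = 5_000,
) -> list[IslandCall]:
    """Call under-recruiting islands from a coverage profile.

    Sliding windows whose mean coverage is below ``ratio_threshold`` times
    the genome-wide median windowed coverage are flagged; flagged windows
    overlapping or within ``merge_gap`` of each other are merged, merged
    intervals shorter than ``min_len`` are dropped, and survivors are
    labelled GI1..GIn left to right.
    """
    cov = profile.coverage
    starts, means = _window_means(cov, window, step)
    median = float(np.median(means))
    if median <= 0:
        warnings.warn(
            f"genome {profile.genome_id!r}: median windowed coverage is zero; "
            "island calling skipped"
        )
        return []
    flagged = means < ratio_threshold * median
    if not flagged.any():
        return []
    # merge flagged windows
    intervals: list[list[int]] = []
    for s in starts[flagged]:
        s = int(s)
        e = s + window
        if intervals and s <= intervals[-1][1] + merge_gap:
            intervals[-1][1] = max(intervals[-1][1], e)
        else:
            intervals.append([s, e])
    calls = []
    n = 0
    for s, e in intervals:
        if e - s < min_len:
            continue
        n += 1
        ratio = float(cov[s:e].mean()) / median
        calls.append(IslandCall(s, e, ratio, f"GI{n}"))
    return calls
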