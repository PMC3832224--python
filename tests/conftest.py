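"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive and self-contained: a full
(unbanded) Smith-Waterman in plain Python and a dense grid scan for
isoelectric points.  They never call into the implementation paths they
check.
"""

from __future__ import annotations

import os

import numpy as np
import pytest
from hypothesis import settings

from streamline_scan.aligner import GAP_EXT, GAP_OPEN, MATCH, MISMATCH

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

REFERENCE_DIR = os.path.join(os.path.dirname(__file__), "..", "data", "reference")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def smith_waterman_score(q: str, s: str) -> int:
    """Exhaustive local alignment score, affine gaps, one strand.

    Same scoring constants as the package aligner (match +1, mismatch -2,
    gap open -5, gap extend -2), full dynamic-programming matrix.
    """
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] + GAP_OPEN, Ei[j - 1] + GAP_EXT)
            f = max(Hi1[j] + GAP_OPEN, Fi1[j] + GAP_EXT)
            sub = MATCH if qi == s[j - 1] else MISMATCH
            h = Hi1[j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Hi[j] = h
            Ei[j] = e
            Fi[j] = f
            if h > best:
                best = h
    return best


def smith_waterman_score_both_strands(q: str, s: str) -> int:
    return max(smith_waterman_score(q, s), smith_waterman_score(revcomp(q), s))


def grid_isoelectric_point(protein: str, step: float = 1e-3) -> float:
    """Brute-force pI: the grid pH minimizing |net charge|.

    Recomputes the charge balance directly from group counts rather than
    going through the package's bisection path.
    """
    pka_basic = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
    pka_acidic = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
    p = protein.upper()
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in "KRHDECY":
        counts[aa] = p.count(aa)
    grid = np.arange(0.0, 14.0 + step / 2, step)
    tp = 10.0 ** grid
    z = np.zeros_like(grid)
    for g, pk in pka_basic.items():
        ka = 10.0 ** pk
        z += counts[g] * ka / (tp + ka)
    for g, pk in pka_acidic.items():
        ka = 10.0 ** pk
        z -= counts[g] * tp / (tp + ka)
    return float(grid[np.argmin(np.abs(z))])


def mutate_string(seq: str, positions, rng) -> str:
    """Substitute each listed position with a different random base."""
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


def reference_genome_path(accession: str):
    """Path of a locally provided deposited GenBank record, or None."""
    for ext in (".gb", ".gbk", ".gbff", ".genbank"):
        p = os.path.join(REFERENCE_DIR, accession + ext)
        if os.path.exists(p):
            return p
    return None


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_genome():
    """A 50-kb annotated synthetic genome reused across unit tests."""
    from streamline_scan import synth

    return synth.generate_genome(50_000, gc=0.62, seed=77, genome_id="unit50k")
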