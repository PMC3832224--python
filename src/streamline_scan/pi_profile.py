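"""Whole-proteome isoelectric-point ("virtual 2D-gel") profiles.

Salt-in halophiles carry strongly acidic proteomes: their pI density
collapses into a single peak near pH 4.5-5, whereas non-halophilic
proteomes are bimodal (an acidic peak for cytoplasmic proteins and a
basic one containing the membrane proteins).  This module computes
per-protein pI by bisection on the Henderson-Hasselbalch net-charge
function, bins the values into a density over the pH axis, and locates
the peaks of a kernel-smoothed version of that density.

The default pKa table is the EMBOSS ``iep`` set.  Net charge at a given
pH is

    Z(pH) = sum_basic  n_g * 10^pKa_g / (10^pH + 10^pKa_g)
          - sum_acidic n_g * 10^pH    / (10^pH + 10^pKa_g)

with basic groups {N-terminus, K, R, H} and acidic groups
{C-terminus, D, E, C, Y}.  Z is strictly decreasing in pH, so the root
on [0, 14] is unique.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .io_formats import AnnotatedGenome

#: EMBOSS iep default pKa values.
EMBOSS_PKA = {
    "Nterm": 8.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "Cterm": 3.6,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_BASIC = ("Nterm", "K", "R", "H")
_ACIDIC = ("Cterm", "D", "E", "C", "Y")


def _group_counts(protein: str) -> dict[str, int]:
    p = protein.upper()
    counts = {"Nterm": 1, "Cterm": 1}
    for aa in ("K", "R", "H", "D", "E", "C", "Y"):
        counts[aa] = p.count(aa)
    return counts


def net_charge(protein: str, pH: float, pka: dict[str, float] = EMBOSS_PKA) -> float:
    """Net charge of a protein at the given pH (unknown residues carry none)."""
    counts = _group_counts(protein)
    ten_ph = 10.0 ** pH
    z = 0.0
    for g in _BASIC:
        ka = 10.0 ** pka[g]
        z += counts[g] * ka / (ten_ph + ka)
    for g in _ACIDIC:
        ka = 10.0 ** pka[g]
        z -= counts[g] * ten_ph / (ten_ph + ka)
    return z


def isoelectric_point(protein: str, pka: dict[str, float] = EMBOSS_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Stops when |Z| < tol or the bracketing interval is narrower than tol.
    """
    if not protein:
        raise ValueError("cannot compute pI of an empty protein")
    lo, hi = 0.0, 14.0
    z_lo = net_charge(protein, lo, pka)
    if z_lo <= 0:
        return lo
    if net_charge(protein, hi, pka) >= 0:
        return hi
    while hi - lo >= tol:
        mid = 0.5 * (lo + hi)
        z = net_charge(protein, mid, pka)
        if abs(z) < tol:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class PIProfile:
    """Per-protein pI values with their binned density for one proteome."""

    genome_id: str
    pi_values: list[float]
    bin_width: float = 0.2
    bandwidth: float = 0.3
    n_excluded: int = 0
    bin_edges: np.ndarray = field(init=False, repr=False)
    counts: np.ndarray = field(init=False, repr=False)
    smoothed: np.ndarray = field(init=False, repr=False)
    peaks: list[float] = field(init=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.arange(0.0, 14.0 + self.bin_width / 2, self.bin_width)
        self.counts, _ = np.histogram(self.pi_values, bins=self.bin_edges)
        sigma = self.bandwidth / self.bin_width
        self.smoothed = gaussian_filter1d(self.counts.astype(float), sigma=sigma,
                                          mode="constant")
        self.peaks = self._find_peaks()

    def _find_peaks(self) -> list[float]:
        sm = self.smoothed
        if sm.max() <= 0:
            return []
        idx, _ = find_peaks(sm, height=0.10 * sm.max(), prominence=0.15 * sm.max())
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return [float(centers[i]) for i in idx]


def proteome_profile(
    genome: AnnotatedGenome,
    pka: dict[str, float] = EMBOSS_PKA,
    bin_width: float = 0.2,
    bandwidth: float = 0.3,
    min_length: int = 10,
) -> PIProfile:
    """pI profile over all CDS translations of a genome.

    Proteins shorter than ``min_length`` residues or containing internal
    stops are excluded (pseudogene fragments distort the density tail);
    the number excluded is recorded on the profile.
    """
    proteins = [f.protein for f in genome.cds if f.protein]
    if not proteins:
        raise ValueError(f"genome {genome.id!r} has no CDS with protein sequence")
    kept, excluded = [], 0
    for p in proteins:
        if len(p) < min_length or "*" in p:
            excluded += 1
        else:
            kept.append(p)
    if not kept:
        raise ValueError(f"genome {genome.id!r}: all proteins failed QC")
    pis = [isoelectric_point(p, pka) for p in kept]
    return PIProfile(genome.id, pis, bin_width, bandwidth, n_excluded=excluded)


def profile_from_proteins(proteins: list[str], genome_id: str = "proteome",
                          **kwargs) -> PIProfile:
    """pI profile straight from a protein list (e.g. a synthetic proteome)."""
    if not proteins:
        raise ValueError("empty protein list")
    pis = [isoelectric_point(p) for p in proteins]
    return PIProfile(genome_id, pis, **kwargs)


def acidity_summary(profile: PIProfile) -> tuple[float, float]:
    """(fraction of proteins with pI < 7, median pI) of a profile."""
    if not profile.pi_values:
        raise ValueError("empty pI profile")
    vals = profile.pi_values
    frac = sum(1 for v in vals if v < 7.0) / len(vals)
    return frac, float(statistics.median(vals))
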