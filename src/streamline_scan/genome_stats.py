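"""Genome-streamlining metrics: GC content, intergenic spacers, coding density.

Dominant planktonic prokaryotes tend to carry compact genomes: short
intergenic spacers (median on the order of tens of nucleotides), high
coding density and few mobile elements.  These three statistics quantify
that signature for a single annotated replicon.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import AnnotatedGenome

DEFAULT_SPACER_KINDS = ("CDS", "rRNA", "tRNA")


@dataclass
class SpacerDistribution:
    """Intergenic-spacer lengths between consecutive features of a genome."""

    genome_id: str
    spacers: list[int]

    @property
    def median(self) -> float:
        if not self.spacers:
            raise ValueError(f"no spacers for genome {self.genome_id!r}")
        return float(statistics.median(self.spacers))


def gc_content(genome: AnnotatedGenome | str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T), case-insensitive.

    N and other ambiguous bases are excluded from the denominator.
    Raises on a sequence with no unambiguous bases.
    """
    seq = genome.sequence if isinstance(genome, AnnotatedGenome) else genome
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / (gc + at)


def intergenic_spacers(
    genome: AnnotatedGenome,
    kinds: Iterable[str] = DEFAULT_SPACER_KINDS,
    policy: str = "clamp",
) -> SpacerDistribution:
    """Spacer lengths between consecutive features, sorted by start, strand-blind.

    ``policy='clamp'`` records overlapping neighbours as spacer 0 (keeps the
    spacer count fixed at #features - 1); ``policy='exclude'`` drops the
    overlapping pairs from the distribution instead.
    """
    if policy not in ("clamp", "exclude"):
        raise ValueError(f"unknown spacer policy {policy!r}")
    feats = genome.features_of_kind(kinds)
    if len(feats) < 2:
        warnings.warn(
            f"genome {genome.id!r}: fewer than 2 features of kinds {tuple(kinds)}; "
            "empty spacer distribution"
        )
        return SpacerDistribution(genome.id, [])
    spacers = []
    for prev, nxt in zip(feats, feats[1:]):
        gap = nxt.start - prev.end
        if gap < 0:
            if policy == "clamp":
                spacers.append(0)
        else:
            spacers.append(gap)
    return SpacerDistribution(genome.id, spacers)


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def coding_density(genome: AnnotatedGenome) -> float:
    """Fraction of the genome covered by the union of CDS intervals."""
    cds = genome.cds
    if not cds:
        raise ValueError(f"genome {genome.id!r} has no CDS features")
    return _union_length([(f.start, f.end) for f in cds]) / len(genome)


def genome_summary(genome: AnnotatedGenome, spacer_policy: str = "clamp") -> dict:
    """One Table-1-style row: size, GC%, CDS count, coding density, median spacer."""
    row: dict[str, object] = {
        "genome": genome.id,
        "length_bp": len(genome),
        "gc_pct": round(gc_content(genome) * 100, 2),
        "cds_count": len(genome.cds),
    }
    try:
        row["coding_density_pct"] = round(coding_density(genome) * 100, 2)
    except ValueError:
        row["coding_density_pct"] = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dist = intergenic_spacers(genome, policy=spacer_policy)
    row["median_spacer_nt"] = dist.median if dist.spacers else ""
    return row
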