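"""Truth-labelled synthetic data: genomes, lineages, islands, reads, proteomes.

The generator emulates the structure of an intermediate-salinity saltern
community seen through shotgun reads: a few genomes at skewed abundances,
clonal microdiversity (co-existing lineages a fraction of a percent to a
few percent diverged from their reference), flexible genomic islands
carried by only part of the population, and fixed-length reads with a
small per-base error rate.  Every stochastic choice flows from one
integer-seeded PCG64 generator (`numpy.random.default_rng`), so any
downstream result is reconstructible from (spec, seed) alone.

Defaults reflect the study conditions being emulated: 100-bp reads
(Illumina HiSeq 2000 era), 0.5% per-base sequencing error, 1% lineage
divergence (reads must still clear a 95%-identity recruitment cut-off,
i.e. "nearly identical microbes"), and streamlined genome layouts
(~900-bp genes separated by geometric spacers with a 15-nt mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._codec import decode, encode
from .io_formats import AnnotatedGenome, Feature, ReadSet

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _translate_codes(codes: np.ndarray) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(decode(codes)).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot


@dataclass
class IslandPlan:
    """A flexible-island interval with its population carriage frequency."""

    start: int
    end: int
    frequency: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.frequency <= 1.0):
            raise ValueError("island frequency must lie in [0, 1]")


@dataclass
class CommunityMember:
    genome: AnnotatedGenome
    abundance: float
    divergence: float = 0.01
    islands: list[IslandPlan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


@dataclass
class CommunitySpec:
    """Full description of a synthetic metagenomic read experiment."""

    members: list[CommunityMember]
    read_length: int = 100
    read_count: int = 10_000
    error_rate: float = 0.005
    n_lineages: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


def generate_genome(
    length: int,
    gc: float = 0.60,
    mean_gene_len: int = 900,
    mean_spacer: int = 15,
    seed: int = 0,
    genome_id: Optional[str] = None,
) -> AnnotatedGenome:
    """Random genome with i.i.d. bases at the target GC and an alternating
    gene/spacer layout (geometric spacer lengths of the stated mean).

    Gene lengths are drawn around ``mean_gene_len`` and rounded to whole
    codons; genes carry standard-code translations of their sequence.
    """
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must lie strictly between 0 and 1")
    if mean_gene_len >= length:
        raise ValueError("mean_gene_len must be smaller than the genome length")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    features: list[Feature] = []
    pos = 0
    while True:
        gene_len = int(rng.normal(mean_gene_len, mean_gene_len / 4))
        gene_len = max(90, (gene_len // 3) * 3)
        if pos + gene_len > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        seg = codes[pos : pos + gene_len]
        if strand == "-":
            seg = (3 - seg)[::-1]
        features.append(Feature(pos, pos + gene_len, strand, "CDS",
                                _translate_codes(seg)))
        pos += gene_len
        spacer = int(rng.geometric(1.0 / mean_spacer)) if mean_spacer > 0 else 0
        pos += spacer
        if pos >= length:
            break
    gid = genome_id or f"synth-{seed}"
    return AnnotatedGenome(gid, decode(codes), "circular", features)


@dataclass
class MutationLog:
    positions: np.ndarray
    old: np.ndarray
    new: np.ndarray

    def __len__(self) -> int:
        return int(self.positions.size)


def mutate_lineage(
    genome: AnnotatedGenome, substitution_rate: float, seed: int,
    lineage_id: Optional[str] = None,
) -> tuple[AnnotatedGenome, MutationLog]:
    """Per-base i.i.d. substitutions at the stated rate (no indels).

    Every substitution replaces a base by one of the three others, so the
    realized Hamming distance equals the log length exactly.  Ambiguous
    (N) positions are never mutated.  Feature intervals are carried over
    unchanged; proteins refer to the reference sequence.
    """
    rng = np.random.default_rng(seed)
    codes = encode(genome.sequence)
    mask = (rng.random(codes.size) < substitution_rate) & (codes < 4)
    idx = np.flatnonzero(mask)
    old = codes[idx].copy()
    shift = rng.integers(1, 4, size=idx.size).astype(np.uint8)
    new = (old + shift) % 4
    mutated = codes.copy()
    mutated[idx] = new
    lid = lineage_id or f"{genome.id}|lineage-{seed}"
    out = AnnotatedGenome(lid, decode(mutated), genome.topology,
                          [Feature(f.start, f.end, f.strand, f.kind, f.protein)
                           for f in genome.features])
    return out, MutationLog(idx, old, new)


def _overlapping_island(pos: np.ndarray, read_len: int,
                        islands: Sequence[IslandPlan]) -> np.ndarray:
    """Index of the island each read interval overlaps (-1 for none)."""
    out = np.full(pos.size, -1, dtype=np.int64)
    for i, isl in enumerate(islands):
        hit = (pos < isl.end) & (pos + read_len > isl.start)
        out[hit & (out == -1)] = i
    return out


def simulate_reads(spec: CommunitySpec) -> ReadSet:
    """Draw a truth-labelled read set from a community specification.

    Reads are allocated to members proportionally to abundance x genome
    length, start positions are uniform, island intervals are sampled
    only at their stated population frequency (frequency 0 means no reads
    originate there), each read comes from one of ``n_lineages`` diverged
    lineage copies of the member genome, and per-base errors are applied
    last.
    """
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    for m in spec.members:
        if rl > len(m.genome):
            raise ValueError(
                f"read length {rl} exceeds genome {m.genome.id!r} of length {len(m.genome)}"
            )
    weights = np.array([m.abundance * len(m.genome) for m in spec.members], float)
    weights /= weights.sum()
    counts = rng.multinomial(spec.read_count, weights)

    reads: list[tuple[str, str]] = []
    truth: dict[str, tuple[str, tuple[int, int], bool]] = {}
    ridx = 0
    for member, n_reads in zip(spec.members, counts):
        if n_reads == 0:
            continue
        glen = len(member.genome)
        # lineage pool: clonal microdiversity around the member reference
        if member.divergence > 0 and spec.n_lineages > 0:
            lineages = [
                encode(mutate_lineage(member.genome, member.divergence,
                                      int(rng.integers(2**31)))[0].sequence)
                for _ in range(spec.n_lineages)
            ]
        else:
            lineages = [encode(member.genome.sequence)]

        # island-aware start positions (rejection sampling)
        pos = rng.integers(0, glen - rl + 1, size=n_reads)
        for _ in range(1000):
            isl = _overlapping_island(pos, rl, member.islands)
            need = np.zeros(n_reads, dtype=bool)
            overlapping = np.flatnonzero(isl >= 0)
            if overlapping.size:
                freqs = np.array([member.islands[i].frequency for i in isl[overlapping]])
                rejected = rng.random(overlapping.size) >= freqs
                need[overlapping[rejected]] = True
            if not need.any():
                break
            pos[need] = rng.integers(0, glen - rl + 1, size=int(need.sum()))
        else:
            raise RuntimeError("island rejection sampling did not converge")
        from_island = _overlapping_island(pos, rl, member.islands) >= 0

        lin_choice = rng.integers(0, len(lineages), size=n_reads)
        strands = rng.random(n_reads) < 0.5
        err_mask = rng.random((n_reads, rl)) < spec.error_rate
        err_shift = rng.integers(1, 4, size=(n_reads, rl)).astype(np.uint8)

        offsets = np.arange(rl)
        for li, lin_codes in enumerate(lineages):
            rows = np.flatnonzero(lin_choice == li)
            if rows.size == 0:
                continue
            mat = lin_codes[pos[rows, None] + offsets]
            rc = strands[rows]
            flipped = mat[rc][:, ::-1].copy()
            acgt = flipped < 4
            flipped[acgt] = 3 - flipped[acgt]
            mat[rc] = flipped
            em = err_mask[rows] & (mat < 4)
            mat[em] = (mat[em] + err_shift[rows][em]) % 4
            for r, row in zip(rows, mat):
                rid = f"r{ridx + r}"
                reads.append((rid, decode(row)))
                truth[rid] = (member.genome.id, (int(pos[r]), int(pos[r]) + rl),
                              bool(from_island[r]))
        ridx += n_reads
    reads.sort(key=lambda t: int(t[0][1:]))
    return ReadSet(reads, truth)


def _freqs(**over: float) -> dict[str, float]:
    f = {aa: 0.05 for aa in _AA}
    f.update(over)
    tot = sum(f.values())
    return {aa: v / tot for aa, v in f.items()}


#: salt-in-like acidic proteome: D+E >= 15% combined, depleted K/R
HALOPHILE_AA_FREQS = _freqs(D=0.085, E=0.085, K=0.025, R=0.025)
#: non-halophile proteomes are a mixture of two compositional classes —
#: a mildly acidic one (cytoplasmic) and a mildly basic one (membrane,
#: ribosomal); that polarization is what makes the pI density bimodal.
FRESHWATER_ACIDIC_FREQS = _freqs(D=0.07, E=0.07, K=0.032, R=0.032)
FRESHWATER_BASIC_FREQS = _freqs(D=0.032, E=0.032, K=0.072, R=0.072)
FRESHWATER_ACIDIC_WEIGHT = 0.6


@dataclass
class ProteomeSample:
    proteins: list[str]
    style: str
    aa_freqs: dict[str, float]


def generate_proteome(style: str, n_proteins: int, seed: int = 0,
                      mean_length: int = 300) -> ProteomeSample:
    """Synthetic proteome in one of two compositional styles.

    ``halophile`` over-weights D/E (>= 15% combined, acidic salt-in-like
    proteome, single peak near pI 4.5-5); ``freshwater`` mixes a mildly
    acidic and a mildly basic compositional class, reproducing the
    bimodal pI split of non-halophile proteomes (peaks near pH 5 and
    pH 9-10).
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list(_AA))
    if style == "halophile":
        class_freqs = [HALOPHILE_AA_FREQS]
        class_p = [1.0]
        recorded = HALOPHILE_AA_FREQS
    elif style == "freshwater":
        class_freqs = [FRESHWATER_ACIDIC_FREQS, FRESHWATER_BASIC_FREQS]
        class_p = [FRESHWATER_ACIDIC_WEIGHT, 1.0 - FRESHWATER_ACIDIC_WEIGHT]
        recorded = {
            aa: FRESHWATER_ACIDIC_WEIGHT * FRESHWATER_ACIDIC_FREQS[aa]
            + (1 - FRESHWATER_ACIDIC_WEIGHT) * FRESHWATER_BASIC_FREQS[aa]
            for aa in _AA
        }
    else:
        raise ValueError(f"unknown proteome style {style!r}")
    ps = [np.array([f[a] for a in _AA]) for f in class_freqs]
    lengths = np.clip(rng.lognormal(np.log(mean_length), 0.35, n_proteins), 50, 3000)
    classes = rng.choice(len(class_freqs), size=n_proteins, p=class_p)
    proteins = [
        "".join(rng.choice(aas, size=int(L), p=ps[c]))
        for L, c in zip(lengths, classes)
    ]
    return ProteomeSample(proteins, style, dict(recorded))
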