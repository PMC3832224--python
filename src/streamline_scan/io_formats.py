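"""Readers and writers for the external formats the pipeline touches.

All coordinates are normalized to a single internal convention on ingest:
0-based, half-open intervals.  GenBank and GFF3 (1-based inclusive) are
converted at the boundary; BED is already 0-based half-open.  Circular
replicons are linearized at position 0 for all downstream computation;
features spanning the origin are not reconstructed.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "other")

# GFF3/GenBank feature types that are containers or file-level records, not
# annotation we want to keep as intervals.
_SKIP_TYPES = {"region", "source", "chromosome", "exon", "mRNA", "remark"}


class FormatError(ValueError):
    """Malformed input file."""


class GenomeValidationError(ValueError):
    """A parsed record violates the internal genome invariants."""


@dataclass(frozen=True)
class Feature:
    """One annotated interval, 0-based half-open.

    ``protein`` is only populated for CDS features: either the deposited
    translation or, failing that, a standard-code translation of the
    spliced nucleotide sequence with the trailing stop removed.
    """

    start: int
    end: int
    strand: str = "+"
    kind: str = "other"
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise GenomeValidationError(
                f"invalid feature interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(f"invalid strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise GenomeValidationError(f"unknown feature kind {self.kind!r}")
        if self.protein is not None and self.kind != "CDS":
            raise GenomeValidationError("protein present on non-CDS feature")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    """A replicon sequence plus its ordered feature intervals."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise GenomeValidationError(f"genome {self.id!r} has empty sequence")
        if self.topology not in ("linear", "circular"):
            raise GenomeValidationError(f"invalid topology {self.topology!r}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        n = len(self.sequence)
        for f in self.features:
            if f.end > n:
                raise GenomeValidationError(
                    f"feature [{f.start}, {f.end}) outside genome {self.id!r} "
                    f"of length {n}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kinds: Iterable[str]) -> list[Feature]:
        ks = set(kinds)
        return [f for f in self.features if f.kind in ks]

    @property
    def cds(self) -> list[Feature]:
        return self.features_of_kind(["CDS"])


@dataclass
class ReadSet:
    """Metagenomic reads, optionally truth-labelled when synthetic.

    ``truth`` maps read id -> (source genome id, (start, end) on the source,
    from_island flag).
    """

    reads: list[tuple[str, str]]
    truth: Optional[Mapping[str, tuple[str, tuple[int, int], bool]]] = None

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.reads]
        if len(ids) != len(set(ids)):
            raise FormatError("duplicate read ids in read set")
        if self.truth is not None:
            extra = set(self.truth) - set(ids)
            if extra:
                raise FormatError(f"truth labels for unknown reads: {sorted(extra)[:3]}")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def total_bases(self) -> int:
        return sum(len(s) for _, s in self.reads)


def _translate_cds(nt: str, strand: str) -> str:
    seq = Seq(nt)
    if strand == "-":
        seq = seq.reverse_complement()
    prot = str(seq.translate(table=11, to_stop=False))
    return prot[:-1] if prot.endswith("*") else prot


def _feature_kind(ftype: str) -> str:
    if ftype in ("CDS", "rRNA", "tRNA"):
        return ftype
    return "other"


def _read_fasta_single(path: str) -> tuple[str, str]:
    records = list(SeqIO.parse(path, "fasta"))
    if len(records) == 0:
        raise FormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise FormatError(f"{path}: expected a single replicon, found {len(records)}")
    rec = records[0]
    return rec.id, str(rec.seq).upper()


def _genome_from_genbank(path: str) -> AnnotatedGenome:
    try:
        records = list(SeqIO.parse(path, "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if len(records) != 1:
        raise FormatError(f"{path}: expected a single GenBank record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("linear", "circular"):
        topology = "linear"
    feats: list[Feature] = []
    for sf in rec.features:
        if sf.type in _SKIP_TYPES:
            continue
        kind = _feature_kind(sf.type)
        start = int(sf.location.start)
        end = int(sf.location.end)
        if start >= end:
            continue  # origin-spanning feature on a linearized replicon
        strand = "-" if sf.location.strand == -1 else "+"
        protein = None
        if kind == "CDS":
            transl = sf.qualifiers.get("translation")
            if transl:
                protein = transl[0]
            else:
                nt = str(sf.extract(rec.seq))
                protein = _translate_cds(nt, "+")  # extract() already applies strand
        feats.append(Feature(start, end, strand, kind, protein))
    return AnnotatedGenome(rec.id, seq, topology, feats)


def _genome_from_gff3(fasta_path: str, gff_path: str) -> AnnotatedGenome:
    import gffutils

    gid, seq = _read_fasta_single(fasta_path)
    try:
        db = gffutils.create_db(
            gff_path,
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises several parse-time types
        raise FormatError(f"{gff_path}: {exc}") from exc
    feats: list[Feature] = []
    for rec in db.all_features():
        if rec.featuretype in _SKIP_TYPES:
            continue
        kind = _feature_kind(rec.featuretype)
        start = rec.start - 1  # GFF3 is 1-based inclusive
        end = rec.end
        strand = "-" if rec.strand == "-" else "+"
        protein = None
        if kind == "CDS":
            if end > len(seq):
                raise GenomeValidationError(
                    f"{gff_path}: CDS [{start}, {end}) outside sequence of length {len(seq)}"
                )
            protein = _translate_cds(seq[start:end], strand)
        feats.append(Feature(start, end, strand, kind, protein))
    return AnnotatedGenome(gid, seq, "linear", feats)


def read_genome(path: str, format: str = "auto", gff: Optional[str] = None) -> AnnotatedGenome:
    """Read a genome with its annotation into the internal representation.

    Parameters
    ----------
    path:
        FASTA or GenBank flat file.
    format:
        ``fasta``, ``genbank``, ``fasta+gff3`` or ``auto`` (sniff by extension).
    gff:
        Companion GFF3 path, required for ``fasta+gff3``.
    """
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        if ext in (".gb", ".gbk", ".gbff", ".genbank"):
            format = "genbank"
        elif gff is not None:
            format = "fasta+gff3"
        else:
            format = "fasta"
    if format == "fasta":
        gid, seq = _read_fasta_single(path)
        return AnnotatedGenome(gid, seq, "linear", [])
    if format == "genbank":
        return _genome_from_genbank(path)
    if format == "fasta+gff3":
        if gff is None:
            raise ValueError("fasta+gff3 format requires a gff path")
        return _genome_from_gff3(path, gff)
    raise ValueError(f"unknown genome format {format!r}")


def read_reads(path: str, format: str = "auto") -> ReadSet:
    """Read metagenomic reads from FASTA or FASTQ (qualities ignored)."""
    if format == "auto":
        ext = os.path.splitext(path)[1].lower()
        format = "fastq" if ext in (".fq", ".fastq") else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown read format {format!r}")
    reads = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, format)]
    return ReadSet(reads)


def write_fasta(records: Sequence[tuple[str, str]], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(intervals: Sequence[tuple[str, int, int, str]], path: str) -> None:
    """Write (chrom, start, end[, name]) intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            chrom, start, end = row[0], row[1], row[2]
            name = row[3] if len(row) > 3 else None
            line = f"{chrom}\t{start}\t{end}"
            if name is not None:
                line += f"\t{name}"
            fh.write(line + "\n")


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_tsv(table: Sequence[Mapping[str, object]], path: str,
              columns: Optional[Sequence[str]] = None) -> None:
    """Write a list of row dicts as TSV with a header row.

    Empty input produces a file with the header only (when columns are
    given) — never an error.
    """
    if columns is None:
        columns = list(table[0].keys()) if table else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in table:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def read_tsv(path: str) -> list[dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for line in fh:
            vals = line.rstrip("\n").split("\t")
            rows.append(dict(zip(header, vals)))
    return rows


def write_gff3(genome: AnnotatedGenome, path: str) -> None:
    """Write features as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for i, f in enumerate(genome.features, 1):
            kind = f.kind if f.kind != "other" else "misc_feature"
            fh.write(
                f"{genome.id}\tstreamline-scan\t{kind}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID=feat{i}\n"
            )


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
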