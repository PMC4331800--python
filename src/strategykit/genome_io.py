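"""Genome and annotation input/output, and strand clustering.

Reads a single phage genome from FASTA or GenBank, gene annotations from
GenBank features or GFF3, derives the divergent strand clusters that organise
σ-factor-encoding phage genomes, and writes promoter/cluster features as BED6
or GFF3.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from Bio import SeqIO

from ._seq import interval_length

Topology = Literal["linear", "circular"]

_IUPAC = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class GenomeRecord:
    """A single (possibly circular) DNA genome."""

    identifier: str
    sequence: str
    topology: Topology = "circular"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _IUPAC
        if bad:
            raise ValueError(f"non-DNA characters in genome: {sorted(bad)!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with 1-based inclusive coordinates.

    On a circular genome a gene may span the origin, represented with
    ``end < start``.
    """

    gene_number: int
    start: int
    end: int
    strand: Literal["+", "-"]
    label: str = ""

    def length(self, genome_length: int) -> int:
        return interval_length(self.start, self.end, genome_length)


@dataclass
class StrandCluster:
    """A maximal run of consecutive same-strand genes."""

    strand: Literal["+", "-"]
    member_gene_numbers: list[int]
    span: tuple[int, int]  # 1-based inclusive, may wrap on circular genomes


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".fa", ".fasta", ".fna"}:
        return "fasta"
    if ext in {".gb", ".gbk", ".genbank", ".gbff"}:
        return "genbank"
    if ext in {".gff", ".gff3"}:
        return "gff3"
    raise ValueError(f"cannot infer format from extension of {path!r}")


def read_genome(
    path: str, format: str | None = None, topology: Topology = "circular"
) -> GenomeRecord:
    """Read exactly one genome record from a FASTA or GenBank file.

    Topology defaults to circular, the architecture phage genomes typically
    adopt upon cell entry.
    """
    fmt = format or _infer_format(path)
    if fmt not in {"fasta", "genbank"}:
        raise ValueError(f"unsupported genome format {fmt!r}")
    records = list(SeqIO.parse(path, fmt))
    if len(records) != 1:
        raise ValueError(f"expected exactly 1 record in {path!r}, found {len(records)}")
    rec = records[0]
    return GenomeRecord(identifier=rec.id, sequence=str(rec.seq), topology=topology)


def write_genome_fasta(genome: GenomeRecord, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.identifier}\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


def _genes_from_genbank(path: str) -> list[GeneAnnotation]:
    rec = SeqIO.read(path, "genbank")
    genes = []
    feats = [f for f in rec.features if f.type == "CDS"]
    if not feats:
        feats = [f for f in rec.features if f.type == "gene"]
    for f in feats:
        start = int(f.location.start) + 1
        end = int(f.location.end)
        strand = "-" if f.location.strand == -1 else "+"
        label = f.qualifiers.get("product", f.qualifiers.get("gene", [""]))[0]
        genes.append(GeneAnnotation(0, start, end, strand, label))
    return genes


def _genes_from_gff3(path: str) -> list[GeneAnnotation]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = list(db.features_of_type("CDS")) or list(db.features_of_type("gene"))
    genes = []
    for f in feats:
        strand = "-" if f.strand == "-" else "+"
        label = f.attributes.get("product", f.attributes.get("Name", [""]))[0]
        genes.append(GeneAnnotation(0, f.start, f.end, strand, label))
    return genes


def read_annotations(
    path: str,
    format: str | None = None,
    genome: GenomeRecord | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotations, sorted by start, gene numbers assigned by order.

    Coordinates are validated against ``genome`` when provided; out-of-range
    coordinates on a linear genome are an error.
    """
    fmt = format or _infer_format(path)
    if fmt == "genbank":
        genes = _genes_from_genbank(path)
    elif fmt == "gff3":
        genes = _genes_from_gff3(path)
    else:
        raise ValueError(f"unsupported annotation format {fmt!r}")
    if not genes:
        raise ValueError(f"no gene features found in {path!r}")
    genes.sort(key=lambda g: (g.start, g.end))
    out = []
    for i, g in enumerate(genes, start=1):
        if genome is not None:
            if g.start < 1 or g.start > genome.length or g.end < 1 or g.end > genome.length:
                raise ValueError(
                    f"gene at {g.start}..{g.end} outside genome of {genome.length} bp"
                )
            if g.end < g.start and genome.topology != "circular":
                raise ValueError(
                    f"origin-spanning gene {g.start}..{g.end} on a linear genome"
                )
        out.append(GeneAnnotation(i, g.start, g.end, g.strand, g.label))
    seen: dict[tuple, int] = {}
    for g in out:
        key = (g.start, g.end, g.strand)
        if key in seen:
            raise ValueError(f"duplicate gene annotation at {g.start}..{g.end}{g.strand}")
        seen[key] = g.gene_number
    return out


def strand_clusters(
    genes: Sequence[GeneAnnotation], topology: Topology = "circular"
) -> list[StrandCluster]:
    """Maximal runs of consecutive same-strand genes, in genomic order.

    On a circular genome the first and last runs are merged when they share a
    strand, since they are contiguous across the origin.
    """
    if not genes:
        raise ValueError("empty gene list")
    clusters: list[StrandCluster] = []
    for g in genes:
        if clusters and clusters[-1].strand == g.strand:
            clusters[-1].member_gene_numbers.append(g.gene_number)
            clusters[-1].span = (clusters[-1].span[0], g.end)
        else:
            clusters.append(StrandCluster(g.strand, [g.gene_number], (g.start, g.end)))
    if (
        topology == "circular"
        and len(clusters) > 1
        and clusters[0].strand == clusters[-1].strand
    ):
        last = clusters.pop()
        first = clusters[0]
        first.member_gene_numbers = last.member_gene_numbers + first.member_gene_numbers
        first.span = (last.span[0], first.span[1])  # wraps: start > end
    return clusters


def write_bed6(
    features: Iterable[tuple[str, int, int, str, float, str]], path: str
) -> None:
    """Write (chrom, start1, end1, name, score, strand) tuples as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in features:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_gff3_features(
    features: Iterable[tuple[str, str, int, int, str, str]], path: str
) -> None:
    """Write (chrom, type, start1, end1, strand, attributes) rows as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, ftype, start, end, strand, attrs in features:
            fh.write(
                f"{chrom}\tstrategykit\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attrs}\n"
            )
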