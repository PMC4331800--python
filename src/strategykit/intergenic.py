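"""Extraction of upstream intergenic regions.

Each region is oriented in its downstream gene's transcription direction, so
that downstream motif searches only ever scan the direct strand (phage
promoter motifs are not palindromic).  Because promoter elements can overlap
the 3' end of the upstream gene, a fixed-length prefix of that gene's 3' end
is fused to the region's 5' end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

from ._seq import circular_slice, interval_length, revcomp, wrap_coord
from .genome_io import GeneAnnotation, GenomeRecord

logger = logging.getLogger(__name__)

Group = Literal["plus", "minus", "all"]


@dataclass(frozen=True)
class IntergenicRegion:
    """An upstream region oriented 5'→3' with the downstream gene.

    ``start``/``end`` are 1-based inclusive forward-strand genomic coordinates
    of the fused region (wrapping through the origin when ``start > end`` on a
    circular genome).  ``sequence`` is the forward slice for "+" downstream
    genes and its reverse complement for "-" genes.
    """

    downstream_gene: int
    upstream_gene: int | None
    sequence: str
    start: int
    end: int
    strand: Literal["+", "-"]
    fused_offset: int
    group: Group
    genome_length: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_genomic(self, local_offset: int) -> int:
        """Forward-strand coordinate of the base at a 0-based local offset.

        Local offsets count along the oriented (transcription-direction)
        sequence, so for "-" regions offset 0 maps to ``end``.
        """
        if not 0 <= local_offset < self.length:
            raise IndexError(f"offset {local_offset} outside region of {self.length} bp")
        if self.strand == "+":
            return wrap_coord(self.start + local_offset, self.genome_length)
        return wrap_coord(self.end - local_offset, self.genome_length)


def _build_region(
    genome: GenomeRecord,
    downstream: GeneAnnotation,
    upstream: GeneAnnotation | None,
    gap_start: int,
    gap_end: int,
    fuse_len: int,
    group: Group,
) -> IntergenicRegion:
    """Fuse ``fuse_len`` bp of the upstream gene's 3' end onto the gap."""
    n = genome.length
    if downstream.strand == "+":
        start = wrap_coord(gap_start - fuse_len, n) if fuse_len else gap_start
        end = gap_end
        seq = circular_slice(genome.sequence, start, end)
    else:
        start = gap_start
        end = wrap_coord(gap_end + fuse_len, n) if fuse_len else gap_end
        seq = revcomp(circular_slice(genome.sequence, start, end))
    return IntergenicRegion(
        downstream_gene=downstream.gene_number,
        upstream_gene=upstream.gene_number if upstream else None,
        sequence=seq,
        start=start,
        end=end,
        strand=downstream.strand,
        fused_offset=fuse_len,
        group=group,
        genome_length=n,
    )


def extract_upstream_regions(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    group: Group = "all",
    min_len: int = 50,
    fuse_len: int = 30,
) -> list[IntergenicRegion]:
    """Extract upstream intergenic regions longer than ``min_len`` bp.

    The length filter applies to the unfused gap (strictly greater than
    ``min_len``); fusion then prepends ``fuse_len`` bp of the upstream
    neighbour's 3' end.  A gap between divergently transcribed genes yields a
    region for each flanking downstream gene when ``group="all"``.  Negative
    gaps (nested/overlapping genes) yield no region.
    """
    if not genes:
        raise ValueError("empty gene list")
    genes = sorted(genes, key=lambda g: (g.start, g.end))
    n = genome.length
    circular = genome.topology == "circular"
    regions: list[IntergenicRegion] = []
    skipped_overlap = 0
    for i, g in enumerate(genes):
        if g.strand == "+" and group == "minus":
            continue
        if g.strand == "-" and group == "plus":
            continue
        if g.strand == "+":
            if i > 0:
                neighbour = genes[i - 1]
            elif circular:
                neighbour = genes[-1]
            else:
                neighbour = None
            if neighbour is None:
                continue
            gap_start = wrap_coord(neighbour.end + 1, n)
            gap_end = wrap_coord(g.start - 1, n)
        else:
            if i < len(genes) - 1:
                neighbour = genes[i + 1]
            elif circular:
                neighbour = genes[0]
            else:
                neighbour = None
            if neighbour is None:
                continue
            gap_start = wrap_coord(g.end + 1, n)
            gap_end = wrap_coord(neighbour.start - 1, n)
        gap_len = _gap_length(g, neighbour, gap_start, gap_end, n)
        if gap_len <= 0:
            skipped_overlap += 1
            continue
        if gap_len <= min_len:
            continue
        regions.append(
            _build_region(genome, g, neighbour, gap_start, gap_end, fuse_len, group)
        )
    if skipped_overlap:
        logger.info("skipped %d overlapping/nested gene pairs", skipped_overlap)
    return regions


def _gap_length(
    gene: GeneAnnotation,
    neighbour: GeneAnnotation,
    gap_start: int,
    gap_end: int,
    n: int,
) -> int:
    """Signed gap length between a gene and its upstream neighbour."""
    if gene.strand == "+":
        raw = gene.start - neighbour.end - 1
    else:
        raw = neighbour.start - gene.end - 1
    if raw < 0 and gene.start != neighbour.start:
        # distinguish a genuine overlap from an origin wrap
        wrapped = interval_length(gap_start, gap_end, n)
        if wrapped <= n // 2:  # plausible wrap; overlaps stay negative
            return wrapped
    return raw


def origin_spanning_region(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    fuse_len: int = 30,
) -> IntergenicRegion:
    """The long intergenic region joining the genome's 3' and 5' ends.

    On a circular phage genome this region separates the two divergent gene
    clusters and is the anchor candidate expected to host at least one
    phage-specific promoter for the "+" (structural/late) cluster.
    """
    if genome.topology != "circular":
        raise ValueError(
            "origin-spanning region requires circular topology; on a linear "
            "genome identify the anchor region manually"
        )
    genes = sorted(genes, key=lambda g: (g.start, g.end))
    last, first = genes[-1], genes[0]
    gap_start = wrap_coord(last.end + 1, genome.length)
    gap_end = wrap_coord(first.start - 1, genome.length)
    gap_len = interval_length(gap_start, gap_end, genome.length)
    if last.end + 1 == first.start or gap_len <= 0 or last.end == genome.length and first.start == 1:
        raise ValueError("zero-length origin-spanning region")
    downstream = first if first.strand == "+" else last
    upstream = last if downstream is first else first
    if downstream.strand == "+":
        return _build_region(genome, downstream, upstream, gap_start, gap_end, fuse_len, "plus")
    return _build_region(genome, downstream, upstream, gap_start, gap_end, fuse_len, "minus")


def regions_to_fasta(regions: Sequence[IntergenicRegion], path: str) -> None:
    """Export regions as multi-FASTA with provenance headers."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f">gene{r.downstream_gene} {r.start}..{r.end}({r.strand}) "
                f"fused={r.fused_offset} group={r.group}\n{r.sequence}\n"
            )
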