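"""Temporal (early/middle/late) gene classification and strategy report.

The inferred infection strategy of a σ-factor-encoding lytic phage follows
from the promoter layout: host-σ70 promoters drive the early genes (upstream
functional cluster, transcribed as a long operon until the anti-sigma factor
silences host RNA polymerase); core-motif ("short") phage promoters drive the
middle genes in the downstream part of the functional cluster; TATA-bearing
("long") phage promoters drive the late structural genes.

Each gene inherits the class of the nearest upstream same-strand promoter
within its strand cluster (operon propagation; cluster boundaries are the
only stop signals since intrinsic terminators are not modelled).  Genes
downstream of both a σ70 and a middle promoter - the σ-factor gene itself is
the canonical case - are labelled middle with a dual-promoter rationale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Sequence

from ._seq import wrap_coord
from .genome_io import GeneAnnotation, GenomeRecord, StrandCluster, strand_clusters
from .sigma70_pwm import SigmaPromoterPrediction
from .supervised_scan import PromoterMotif

TemporalClass = Literal["early", "middle", "late", "unassigned"]

_CLASS_OF_PROMOTER = {
    "sigma70": "early",
    "middle_short": "middle",
    "late_long": "late",
}


@dataclass(frozen=True)
class PromoterEvent:
    """A promoter reduced to what temporal propagation needs."""

    kind: Literal["sigma70", "middle_short", "late_long"]
    coordinate: int  # 1-based forward-strand anchor
    strand: Literal["+", "-"]
    label: str = ""


@dataclass
class TemporalAssignment:
    gene_number: int
    temporal_class: TemporalClass
    supporting_promoters: list[PromoterEvent] = field(default_factory=list)
    rationale: str = ""


def _as_events(
    sigma70_predictions: Sequence[SigmaPromoterPrediction],
    phage_motifs: Sequence[PromoterMotif],
) -> list[PromoterEvent]:
    events = []
    for p in sigma70_predictions:
        # anchor at the 5' end in transcription direction
        coord = p.start if p.strand == "+" else p.end
        events.append(PromoterEvent("sigma70", coord, p.strand, f"score={p.score:.2f}"))
    for m in phage_motifs:
        events.append(
            PromoterEvent(m.promoter_class, m.genomic_coordinate, m.strand, m.sequence)
        )
    return events


def _transcription_order(
    cluster: StrandCluster, genes_by_number: dict[int, GeneAnnotation]
) -> list[GeneAnnotation]:
    members = [genes_by_number[n] for n in cluster.member_gene_numbers]
    return members if cluster.strand == "+" else list(reversed(members))


def _upstream_distance(
    promoter: PromoterEvent, gene: GeneAnnotation, genome_length: int
) -> int | None:
    """Distance from the promoter to the gene's 5' end when the promoter lies
    upstream on the gene's strand (circular wrap allowed); None otherwise."""
    if promoter.strand != gene.strand:
        return None
    if gene.strand == "+":
        d = (gene.start - promoter.coordinate) % genome_length
    else:
        d = (promoter.coordinate - gene.end) % genome_length
    return d


def classify_genes_temporal(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    sigma70_predictions: Sequence[SigmaPromoterPrediction] = (),
    phage_motifs: Sequence[PromoterMotif] = (),
) -> list[TemporalAssignment]:
    """Assign every gene a temporal class by operon propagation.

    Walking each strand cluster in transcription order, a gene takes the
    class of the most recently passed same-strand promoter; genes reached by
    both a σ70 (early) and a middle promoter are middle, with a dual-promoter
    rationale.  Genes upstream of every promoter in their cluster remain
    unassigned.
    """
    if not genes:
        raise ValueError("empty gene list")
    events = _as_events(sigma70_predictions, phage_motifs)
    genes_sorted = sorted(genes, key=lambda g: (g.start, g.end))
    genes_by_number = {g.gene_number: g for g in genes}
    clusters = strand_clusters(genes_sorted, genome.topology)
    n = genome.length
    assignments: dict[int, TemporalAssignment] = {}
    for cluster in clusters:
        ordered = _transcription_order(cluster, genes_by_number)
        first = ordered[0]
        # upstream boundary of the cluster: just past the adjacent annotated
        # gene (any strand) upstream of the cluster's first-transcribed gene;
        # promoters between that boundary and a gene's 5' end are "passed"
        if cluster.strand == "+":
            idx = genes_sorted.index(first)
            prev = genes_sorted[idx - 1] if (idx > 0 or genome.topology == "circular") else None
            boundary = wrap_coord(prev.end + 1, n) if prev is not None else 1
        else:
            idx = genes_sorted.index(first)
            nxt = (
                genes_sorted[(idx + 1) % len(genes_sorted)]
                if (idx + 1 < len(genes_sorted) or genome.topology == "circular")
                else None
            )
            boundary = wrap_coord(nxt.start - 1, n) if nxt is not None else n
        for gene in ordered:
            if cluster.strand == "+":
                extent = (gene.start - boundary) % n
            else:
                extent = (boundary - gene.end) % n
            passed: list[tuple[int, PromoterEvent]] = []
            for ev in events:
                d = _upstream_distance(ev, gene, n)
                if d is not None and d <= extent:
                    passed.append((d, ev))
            passed.sort(key=lambda t: (-t[0], t[1].coordinate))  # farthest first
            kinds = {e.kind for _, e in passed}
            if not passed:
                assignments[gene.gene_number] = TemporalAssignment(
                    gene.gene_number, "unassigned", [], "no upstream promoter in cluster"
                )
                continue
            nearest = passed[-1][1]
            if "sigma70" in kinds and "middle_short" in kinds:
                cls: TemporalClass = "middle"
                rationale = (
                    "dual promoters: transcribed early from a host promoter and "
                    "later from a phage middle promoter"
                )
                support = [e for _, e in passed if e.kind in ("sigma70", "middle_short")]
            else:
                cls = _CLASS_OF_PROMOTER[nearest.kind]  # type: ignore[assignment]
                rationale = f"nearest upstream promoter is {nearest.kind}"
                support = [nearest]
            assignments[gene.gene_number] = TemporalAssignment(
                gene.gene_number, cls, list(support), rationale
            )
    return [assignments[g.gene_number] for g in genes]


def strategy_report(
    genome: GenomeRecord,
    assignments: Sequence[TemporalAssignment],
    sigma70_predictions: Sequence[SigmaPromoterPrediction] = (),
    phage_motifs: Sequence[PromoterMotif] = (),
) -> dict:
    """Machine-readable infection-strategy report.

    Contains the promoter layout ordered by coordinate, contiguous temporal
    class blocks in gene order, per-class counts, and a short narrative
    skeleton.  Deterministic for identical inputs.
    """
    events = _as_events(sigma70_predictions, phage_motifs)
    layout = [
        {
            "kind": e.kind,
            "coordinate": e.coordinate,
            "strand": e.strand,
            "label": e.label,
        }
        for e in sorted(events, key=lambda e: (e.coordinate, e.kind, e.strand))
    ]
    counts = {"early": 0, "middle": 0, "late": 0, "unassigned": 0}
    for a in assignments:
        counts[a.temporal_class] += 1
    blocks: list[dict] = []
    for a in sorted(assignments, key=lambda x: x.gene_number):
        if blocks and blocks[-1]["temporal_class"] == a.temporal_class:
            blocks[-1]["genes"].append(a.gene_number)
        else:
            blocks.append({"temporal_class": a.temporal_class, "genes": [a.gene_number]})
    no_promoters = not events
    narrative = []
    if no_promoters:
        narrative.append(
            "No promoters supplied: all genes unassigned; the inference failed."
        )
    else:
        if counts["early"]:
            narrative.append(
                f"{counts['early']} early genes transcribed by host RNA polymerase "
                "from sigma70 promoters, likely as a long operon."
            )
        if counts["middle"]:
            narrative.append(
                f"{counts['middle']} middle genes transcribed by the phage sigma "
                "factor from core-motif (short) promoters after host shut-off."
            )
        if counts["late"]:
            narrative.append(
                f"{counts['late']} late genes (structural cluster) transcribed from "
                "TATA-bearing (long) phage promoters."
            )
        if counts["unassigned"]:
            narrative.append(f"{counts['unassigned']} genes could not be assigned.")
    return {
        "genome": {"identifier": genome.identifier, "length": genome.length,
                   "topology": genome.topology},
        "promoter_layout": layout,
        "class_counts": counts,
        "class_blocks": blocks,
        "assignments": [
            {
                "gene_number": a.gene_number,
                "temporal_class": a.temporal_class,
                "rationale": a.rationale,
            }
            for a in sorted(assignments, key=lambda x: x.gene_number)
        ],
        "failed": no_promoters,
        "narrative": " ".join(narrative),
    }


def report_to_json(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def assignments_to_gff3(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    assignments: Sequence[TemporalAssignment],
    path: str,
) -> None:
    """Write genes with their temporal class as a GFF3 attribute."""
    cls = {a.gene_number: a.temporal_class for a in assignments}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: x.gene_number):
            end = g.end if g.end >= g.start else genome.length  # truncate wraps
            fh.write(
                f"{genome.identifier}\tstrategykit\tgene\t{g.start}\t{end}\t.\t"
                f"{g.strand}\t.\tID=gene{g.gene_number};"
                f"temporal_class={cls.get(g.gene_number, 'unassigned')}\n"
            )
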