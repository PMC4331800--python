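import numpy as np
import pytest

from strategykit.genome_io import GeneAnnotation, GenomeRecord
from strategykit.sigma70_pwm import SigmaPromoterPrediction
from strategykit.supervised_scan import PromoterMotif
from strategykit.temporal_strategy import (
    classify_genes_temporal,
    strategy_report,
)

from conftest import random_dna


def _genome(n=2000, seed=1, topology="linear"):
    return GenomeRecord("toy", random_dna(np.random.default_rng(seed), n), topology)


def _sigma(coord_start, strand="-"):
    # a 29 bp promoter whose transcription-direction 5' end anchors the event
    return SigmaPromoterPrediction(
        "TTGACA", 17, "TATAAT", coord_start, coord_start + 28, strand, -1.0
    )


def _motif(coord, cls, strand="-"):
    return PromoterMotif(0, "TGTGATGTTATA" if cls == "late_long" else "AGTGATGTGTAA",
                         coord, cls, strand)


MINUS_GENES = [
    GeneAnnotation(1, 100, 400, "-"),
    GeneAnnotation(2, 500, 800, "-"),
    GeneAnnotation(3, 900, 1200, "-"),
]


def test_sigma70_propagates_early_through_cluster():
    genome = _genome()
    # '-' genes transcribe right-to-left; promoter upstream = higher coords
    preds = [_sigma(1300)]  # anchor at 1328
    out = classify_genes_temporal(genome, MINUS_GENES, preds, [])
    assert [a.temporal_class for a in out] == ["early", "early", "early"]


def test_middle_motif_flips_downstream_genes():
    genome = _genome()
    preds = [_sigma(1300)]
    motifs = [_motif(850, "middle_short")]  # between gene 3 and gene 2
    out = classify_genes_temporal(genome, MINUS_GENES, preds, motifs)
    by = {a.gene_number: a for a in out}
    assert by[3].temporal_class == "early"
    assert by[2].temporal_class == "middle"
    assert by[1].temporal_class == "middle"
    assert "dual" in by[2].rationale


def test_dual_promoter_gene_labeled_middle():
    genome = _genome()
    # sigma70 nearer than the middle motif: still middle, with dual rationale
    preds = [_sigma(1400)]
    motifs = [_motif(1500, "middle_short")]
    out = classify_genes_temporal(genome, MINUS_GENES, preds, motifs)
    by = {a.gene_number: a for a in out}
    assert by[3].temporal_class == "middle"
    assert "dual" in by[3].rationale
    assert {e.kind for e in by[3].supporting_promoters} == {"sigma70", "middle_short"}


def test_late_promoters_drive_plus_cluster():
    genome = _genome(topology="circular")
    genes = [
        GeneAnnotation(1, 200, 500, "+"),
        GeneAnnotation(2, 600, 900, "+"),
        GeneAnnotation(3, 1000, 1300, "-"),
    ]
    motifs = [_motif(100, "late_long", strand="+")]
    out = classify_genes_temporal(genome, genes, [], motifs)
    by = {a.gene_number: a.temporal_class for a in out}
    assert by[1] == "late" and by[2] == "late"
    assert by[3] == "unassigned"


def test_no_upstream_promoter_unassigned():
    genome = _genome()
    out = classify_genes_temporal(genome, MINUS_GENES, [], [])
    assert all(a.temporal_class == "unassigned" for a in out)


def test_removing_middle_motifs_reverts_to_early_or_unassigned():
    genome = _genome()
    preds = [_sigma(1300)]
    motifs = [_motif(850, "middle_short")]
    with_mid = classify_genes_temporal(genome, MINUS_GENES, preds, motifs)
    without = classify_genes_temporal(genome, MINUS_GENES, preds, [])
    for a, b in zip(with_mid, without):
        if a.temporal_class == "middle":
            assert b.temporal_class in ("early", "unassigned")


def test_assignment_total_and_deterministic(sim_genome, sigma70_model):
    from strategykit.pipeline import discover_phage_promoters, predict_sigma70

    genome, genes, _ = sim_genome
    disc = discover_phage_promoters(genome, genes)
    preds, _, _ = predict_sigma70(genome, genes, sigma70_model, required_minus=8)
    a1 = classify_genes_temporal(genome, genes, preds, disc.promoters)
    a2 = classify_genes_temporal(genome, genes, preds, disc.promoters)
    assert [x.gene_number for x in a1] == [g.gene_number for g in genes]
    assert [(x.gene_number, x.temporal_class) for x in a1] == [
        (x.gene_number, x.temporal_class) for x in a2
    ]


def test_report_flags_empty_promoter_set():
    genome = _genome()
    assignments = classify_genes_temporal(genome, MINUS_GENES, [], [])
    rep = strategy_report(genome, assignments, [], [])
    assert rep["failed"] is True
    assert rep["class_counts"]["unassigned"] == 3


def test_report_layout_matches_expected_architecture(sim_genome, sigma70_model):
    """Late promoters upstream of the '+' cluster, sigma70 upstream of the
    '-' cluster, middle motifs within its downstream part."""
    from strategykit.pipeline import run_pipeline

    genome, genes, _ = sim_genome
    rep = run_pipeline(genome, genes, sigma70_model=sigma70_model)
    counts = rep["class_counts"]
    assert counts["late"] == 5  # the whole '+' (structural) cluster
    assert counts["middle"] >= 1
    assert counts["early"] >= 1
    assert counts["unassigned"] == 0
    blocks = rep["class_blocks"]
    assert blocks[0]["temporal_class"] == "late"
    assert rep["failed"] is False
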