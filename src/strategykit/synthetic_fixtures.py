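"""Synthetic circular phage genomes with planted promoters and truth records.

The generator emulates the genome architecture of σ-factor-encoding lytic
phages: a circular genome with two divergently transcribed gene clusters - a
"+" cluster of structural (late) genes and a "-" cluster of functional genes
- separated at the origin by a long intergenic region.  Late (TATA-bearing,
default template ``TGTGATGTTATA``) promoter motifs are planted in the
origin-spanning region upstream of the "+" cluster; host-σ70 promoters are
planted on the "-" strand upstream of the functional cluster (also in the
origin region, on the complementary strand); middle (core-only) motifs are
planted in intergenic gaps in the downstream part of the "-" cluster.  Every
planted feature is recorded in a truth set so each pipeline stage can be
scored by precision/recall without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._seq import BASES, revcomp
from .genome_io import GeneAnnotation, GenomeRecord
from .sigma70_pwm import OPTIMAL_SPACER, TrainingPromoter

CONSENSUS_35 = "TTGACA"
CONSENSUS_10 = "TATAAT"

# Default per-position probability of the consensus base for the synthetic
# sigma70 training model; remaining mass split evenly over the other bases.
# Conservation is strongest at the outer positions of both hexamers, the
# familiar pattern of E. coli sigma70 alignments.
DEFAULT_CONS_35 = (0.82, 0.82, 0.70, 0.58, 0.55, 0.55)
DEFAULT_CONS_10 = (0.80, 0.88, 0.58, 0.60, 0.55, 0.88)
DEFAULT_SPACER_PROBS = {16: 0.2, 17: 0.6, 18: 0.2}


@dataclass(frozen=True)
class TruthFeature:
    feature_type: Literal["late_promoter", "middle_promoter", "sigma70_promoter"]
    coordinate: int  # 1-based forward-strand anchor (class convention)
    strand: Literal["+", "-"]
    sequence: str  # oriented in transcription direction
    temporal_class: Literal["early", "middle", "late"]


@dataclass
class TruthSet:
    features: list[TruthFeature] = field(default_factory=list)

    def of_type(self, feature_type: str) -> list[TruthFeature]:
        return [f for f in self.features if f.feature_type == feature_type]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated genome."""

    genome_length: int = 20_000
    n_plus_genes: int = 5
    n_minus_genes: int = 15
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    late_motif: str = "TGTGATGTTATA"
    late_copies: int = 4
    late_mutation_rate: float = 0.0
    middle_copies: int = 3
    middle_mutation_rate: float = 0.0
    sigma70_count: int = 8
    cons_35: tuple[float, ...] = DEFAULT_CONS_35
    cons_10: tuple[float, ...] = DEFAULT_CONS_10
    spacer_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SPACER_PROBS)
    )
    origin_region_len: int = 1_600
    mean_gene_len: float = 600.0
    sigma_gene_len: float = 0.35  # log-normal shape: most genes several hundred bp
    intergenic_gap: int = 120
    seed: int = 0


def _random_seq(rng: np.random.Generator, n: int, background) -> str:
    p = np.asarray(background, float)
    p = p / p.sum()
    return "".join(rng.choice(list(BASES), size=n, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != c]))
        else:
            out.append(c)
    return "".join(out)


def _sample_element(rng, consensus: str, cons_probs: Sequence[float]) -> str:
    out = []
    for c, p in zip(consensus, cons_probs):
        if rng.random() < p:
            out.append(c)
        else:
            out.append(rng.choice([b for b in BASES if b != c]))
    return "".join(out)


def simulate_training_promoters(
    n: int,
    seed: int,
    cons_35: Sequence[float] = DEFAULT_CONS_35,
    cons_10: Sequence[float] = DEFAULT_CONS_10,
    spacer_probs: dict[int, float] | None = None,
    consensus_35: str = CONSENSUS_35,
    consensus_10: str = CONSENSUS_10,
) -> list[TrainingPromoter]:
    """Sample a σ70 training alignment from a known independent-column model.

    Stands in for a curated large-scale promoter alignment; with
    ``cons_* = 1`` every sequence equals the consensus.
    """
    if n < 10:
        raise ValueError("need n >= 10")
    rng = np.random.default_rng(seed)
    spacer_probs = dict(spacer_probs or DEFAULT_SPACER_PROBS)
    lens = sorted(spacer_probs)
    probs = np.array([spacer_probs[l] for l in lens], float)
    probs /= probs.sum()
    out = []
    for _ in range(n):
        m35 = _sample_element(rng, consensus_35, cons_35)
        m10 = _sample_element(rng, consensus_10, cons_10)
        spacer = int(rng.choice(lens, p=probs))
        out.append(TrainingPromoter(m35, spacer, m10))
    return out


def _lay_genes(
    rng: np.random.Generator, cfg: SimConfig
) -> tuple[list[GeneAnnotation], list[tuple[int, int]]]:
    """Place the two divergent clusters; returns genes and the middle-motif
    host gaps (1-based inclusive intervals within the "-" cluster)."""
    L = cfg.genome_length
    pos = cfg.origin_region_len + 1  # "+" cluster starts after the origin region
    genes: list[GeneAnnotation] = []
    num = 1

    def gene_len() -> int:
        return max(120, int(rng.lognormal(np.log(cfg.mean_gene_len), cfg.sigma_gene_len)))

    for _ in range(cfg.n_plus_genes):
        glen = gene_len()
        genes.append(GeneAnnotation(num, pos, pos + glen - 1, "+"))
        num += 1
        pos += glen + cfg.intergenic_gap
    pos += 200  # tail gap between the divergent cluster 3' ends
    middle_gaps: list[tuple[int, int]] = []
    for k in range(cfg.n_minus_genes):
        glen = gene_len()
        genes.append(GeneAnnotation(num, pos, pos + glen - 1, "-"))
        num += 1
        gap_start = pos + glen + 1
        pos += glen + cfg.intergenic_gap
        gap_end = pos - 1
        if k < cfg.n_minus_genes - 1:
            middle_gaps.append((gap_start, gap_end))
    tail_gap = L - (pos - cfg.intergenic_gap)  # from last gene end to L
    if tail_gap < 400:
        raise ValueError(
            "infeasible packing: genes overrun the genome; increase genome_length"
        )
    return genes, middle_gaps


def simulate_phage_genome(
    config: SimConfig,
) -> tuple[GenomeRecord, list[GeneAnnotation], TruthSet]:
    """Generate one circular phage-like genome with planted promoters.

    Deterministic per seed; the truth set records every planted feature with
    the anchor conventions the discovery pipeline reports (window start for
    late motifs, core start for middle motifs, -35 start in transcription
    direction for σ70 promoters).
    """
    rng = np.random.default_rng(config.seed)
    genes, middle_gaps = _lay_genes(rng, config)
    L = config.genome_length
    seq = list(_random_seq(rng, L, config.background))
    truth = TruthSet()

    def plant_forward(coord1: int, motif: str) -> None:
        for k, c in enumerate(motif):
            seq[(coord1 - 1 + k) % L] = c

    # --- late motifs: origin region, oriented "+", upstream of gene 1 ---
    first_plus_start = genes[0].start
    window = first_plus_start - 1 - 60  # leave room before the gene
    late_positions = np.linspace(80, window - len(config.late_motif), config.late_copies)
    for p in sorted(set(int(x) for x in late_positions)):
        motif = _mutate(rng, config.late_motif, config.late_mutation_rate)
        plant_forward(p, motif)
        truth.features.append(
            TruthFeature("late_promoter", p, "+", motif, "late")
        )

    # --- sigma70 promoters: "-" strand, upstream of the "-" cluster's first
    # transcribed gene, i.e. in the origin-spanning region at high coords ---
    last_minus_end = max(g.end for g in genes if g.strand == "-")
    space_lo, space_hi = last_minus_end + 40, L - 40
    n_slots = config.sigma70_count
    slot_w = (space_hi - space_lo) // max(n_slots, 1)
    for s in range(n_slots):
        # the first two plants are exact consensus (the strong promoters that
        # carry most early transcription); the rest carry one substitution in
        # a weakly constrained column - functional promoters stay above the
        # genomic background, deviating where the constraint is lowest
        m35, m10 = CONSENSUS_35, CONSENSUS_10
        if s >= 2:
            which = int(rng.integers(0, 2))
            probs = config.cons_35 if which == 0 else config.cons_10
            weak = [i for i, p in enumerate(probs) if p <= 0.6]
            if not weak:
                weak = [int(np.argmin(probs))]
            pos = int(rng.choice(weak))
            elem = list(m35 if which == 0 else m10)
            elem[pos] = rng.choice([b for b in BASES if b != elem[pos]])
            if which == 0:
                m35 = "".join(elem)
            else:
                m10 = "".join(elem)
        spacer = OPTIMAL_SPACER
        prom = m35 + _random_seq(rng, spacer, config.background) + m10
        fwd = revcomp(prom)  # promoter reads 5'->3' on the "-" strand
        start1 = space_lo + s * slot_w
        plant_forward(start1, fwd)
        # anchor: -35 start in transcription direction = forward-strand end
        anchor = start1 + len(prom) - 1
        truth.features.append(
            TruthFeature("sigma70_promoter", anchor, "-", prom, "early")
        )

    # --- middle motifs: downstream (low-coordinate) "-" cluster gaps ---
    core = config.late_motif[2:8]
    for (gap_start, gap_end) in middle_gaps[: config.middle_copies]:
        oriented = (
            _random_seq(rng, 2, config.background)
            + core
            + _random_seq(rng, 1, config.background)
            + "GT"  # never TATA: keeps the short/middle class
            + _random_seq(rng, 1, config.background)
        )
        oriented = _mutate(rng, oriented, config.middle_mutation_rate)
        fwd = revcomp(oriented)
        mid = (gap_start + gap_end) // 2
        start1 = mid - len(fwd) // 2
        plant_forward(start1, fwd)
        end1 = start1 + len(fwd) - 1
        core_anchor = end1 - 2  # core 5' end in "-" orientation
        truth.features.append(
            TruthFeature("middle_promoter", core_anchor, "-", oriented, "middle")
        )

    genome = GenomeRecord(
        identifier=f"simphage_seed{config.seed}",
        sequence="".join(seq),
        topology="circular",
    )
    return genome, genes, truth


def evaluate_against_truth(
    predictions: Sequence[tuple[str, int, str]],
    truth: TruthSet,
    tolerance: int = 3,
    feature_types: Sequence[str] | None = None,
) -> tuple[float, float, bool]:
    """Precision/recall of (feature_type, coordinate, strand) predictions.

    A true positive requires matching type and strand and a coordinate within
    ``tolerance`` bp.  Returns ``(precision, recall, defined)``; with no
    predictions precision is reported as 0.0 with ``defined=False``.
    """
    feats = [
        f
        for f in truth.features
        if feature_types is None or f.feature_type in feature_types
    ]
    preds = [
        p
        for p in predictions
        if feature_types is None or p[0] in feature_types
    ]
    if not preds:
        return 0.0, 0.0 if feats else 1.0, False
    matched_truth: set[int] = set()
    tp = 0
    for ptype, coord, strand in preds:
        hit = None
        for i, f in enumerate(feats):
            if i in matched_truth:
                continue
            if f.feature_type == ptype and f.strand == strand and abs(f.coordinate - coord) <= tolerance:
                hit = i
                break
        if hit is not None:
            matched_truth.add(hit)
            tp += 1
    precision = tp / len(preds)
    recall = tp / len(feats) if feats else 1.0
    return precision, recall, True
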