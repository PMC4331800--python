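"""End-to-end orchestration: genome -> promoters -> temporal strategy.

Chains the discovery stages exactly as they are meant to be run on a new
phage genome: extract and orient intergenic regions, pairwise-align the
anchor (origin-spanning) region to find the low-copy conserved repeat, rescan
all regions with the repeat's core hexamer, classify long/late vs
middle/short motifs, scan for host-σ70 promoters with a strand-bias-selected
threshold, and propagate promoter classes onto genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .genome_io import GeneAnnotation, GenomeRecord
from .intergenic import extract_upstream_regions, origin_spanning_region
from .pairwise_repeat import (
    AlignScoring,
    CandidateMotifSet,
    consolidate_motifs,
    repeat_search,
)
from .sigma70_pwm import (
    PromoterModel,
    SigmaPromoterPrediction,
    scan_genome,
    threshold_by_strand_bias,
)
from .supervised_scan import (
    CandidateWindow,
    PromoterMotif,
    build_profile,
    classify_long_short,
    core_scan,
    window_pvalue,
)
from .temporal_strategy import classify_genes_temporal, strategy_report

logger = logging.getLogger(__name__)


def _best_window_frame(seqs: Sequence[str], width: int = 12) -> int:
    """Offset of the ``width``-column window with maximal per-column majority
    agreement across equal-length instance sequences; 0 when not applicable.

    Consolidated repeat instances can carry a base or two of chance flanking
    extension; the classification conventions (TG prefix / core / TATA
    suffix) assume the conserved 12-bp frame, which is the one whose columns
    agree best across copies.
    """
    if not seqs:
        return 0
    L = len(seqs[0])
    if L <= width:
        return 0
    best_o, best_score = 0, -1.0
    for o in range(L - width + 1):
        score = 0.0
        for p in range(o, o + width):
            counts: dict[str, int] = {}
            for s in seqs:
                counts[s[p]] = counts.get(s[p], 0) + 1
            score += max(counts.values()) / len(seqs)
        if score > best_score:
            best_score, best_o = score, o
    return best_o


@dataclass
class DiscoveryResult:
    motif_sets: list[CandidateMotifSet]
    promoters: list[PromoterMotif]
    core: str | None
    search_space: int


def discover_phage_promoters(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    scoring: AlignScoring = AlignScoring(),
    max_evalue: float = 1e-3,
    scan_pvalue: float = 0.05,
    supervised_group: str = "all",
    mode: str = "anchor",
) -> DiscoveryResult:
    """Discover phage-specific promoters and classify them long/short.

    The pairwise search runs over "+" intergenic regions with the
    origin-spanning region as anchor; motif sets above ``max_evalue`` are
    discarded.  The best set's core (consensus positions 3-8) then drives a
    supervised scan over ``supervised_group`` regions, with candidate windows
    kept at exact-score p < ``scan_pvalue`` against the long-motif profile.
    """
    plus_regions = extract_upstream_regions(genome, genes, group="plus")
    anchor = None
    if genome.topology == "circular":
        osr = origin_spanning_region(genome, genes)
        for r in plus_regions:
            if r.downstream_gene == osr.downstream_gene:
                anchor = r
                break
        if anchor is None and osr.strand == "+":
            plus_regions = [osr] + plus_regions
            anchor = osr
    if anchor is None:
        anchor = plus_regions[0] if plus_regions else None
    if anchor is None:
        return DiscoveryResult([], [], None, 0)
    search_space = sum(r.length for r in plus_regions)
    hits = repeat_search(plus_regions, mode=mode, scoring=scoring, anchor=anchor)
    motif_sets = [
        s for s in consolidate_motifs(hits, search_space) if s.evalue <= max_evalue
    ]
    if not motif_sets:
        logger.warning("no significant repeat found (anchor mode)")
        return DiscoveryResult([], [], None, search_space)
    best = motif_sets[0]
    frame = _best_window_frame(
        [s for (_, _, _, s) in best.instances if len(s) == len(best.consensus)]
    )
    long_windows = [
        s[frame : frame + 12] for (_, _, _, s) in best.instances
        if len(s) >= frame + 12
    ]
    cons12 = best.consensus[frame : frame + 12]
    core = cons12[2:8] if len(cons12) >= 8 else best.consensus
    scan_regions = extract_upstream_regions(genome, genes, group=supervised_group)
    candidates = core_scan(scan_regions, core=core)
    profile = build_profile(long_windows) if len(long_windows) >= 2 else None
    kept: list[CandidateWindow] = []
    pvals: list[float] = []
    seen: set[tuple[int, str]] = set()
    for w in candidates:
        p = window_pvalue(w.window, profile) if profile is not None else 0.0
        if p < scan_pvalue:
            key = (w.genomic_coordinate, w.region.strand)
            if key not in seen:
                seen.add(key)
                kept.append(w)
                pvals.append(p)
    promoters = classify_long_short(kept, pvals)
    # fold in initially discovered instances the scan may have missed
    # (e.g. cores mismatching the consensus hexamer)
    existing = {(m.genomic_coordinate, m.strand) for m in promoters}
    for region, off, coord, s in best.instances:
        if region is None or len(s) < frame + 12:
            continue
        w = CandidateWindow(
            region, s[frame : frame + 12], off + frame, region.to_genomic(off + frame)
        )
        motif = classify_long_short([w])[0]
        key_long = (motif.genomic_coordinate, motif.strand)
        if key_long not in existing:
            existing.add(key_long)
            promoters.append(motif)
    promoters.sort(key=lambda m: (m.promoter_class, m.genomic_coordinate))
    return DiscoveryResult(motif_sets, promoters, core, search_space)


def predict_sigma70(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    model: PromoterModel,
    required_minus: int | None = None,
    max_plus: int = 0,
    permissive_threshold: float = -12.0,
) -> tuple[list[SigmaPromoterPrediction], float, str | None]:
    """σ70 scan over intergenic spans with a strand-bias-selected threshold.

    Scans every extracted intergenic span (plus the fused overhangs) on both
    strands at a permissive threshold, then tightens the threshold to the
    most permissive value leaving at most ``max_plus`` "+"-strand calls.
    Returns the retained predictions, the threshold, and any warning.
    """
    regions = extract_upstream_regions(genome, genes, group="all")
    preds: list[SigmaPromoterPrediction] = []
    seen: set[tuple[int, str]] = set()
    for r in regions:
        if r.start <= r.end:
            slice_seq = genome.sequence[r.start - 1 : r.end]
            offset = r.start - 1
        else:  # origin wrap: scan the unrolled slice
            slice_seq = genome.sequence[r.start - 1 :] + genome.sequence[: r.end]
            offset = r.start - 1
        for p in scan_genome(slice_seq, model, permissive_threshold, offset=offset):
            key = (p.start, p.strand)
            if key not in seen:
                seen.add(key)
                preds.append(p)
    if not preds:
        return [], permissive_threshold, "no windows above the permissive threshold"
    threshold, n_minus, n_plus, warning = threshold_by_strand_bias(
        preds, required_minus=required_minus, max_plus=max_plus
    )
    kept = [p for p in preds if p.score >= threshold]
    kept.sort(key=lambda p: (p.start, p.strand))
    return kept, threshold, warning


def run_pipeline(
    genome: GenomeRecord,
    genes: Sequence[GeneAnnotation],
    sigma70_model: PromoterModel | None = None,
    **discovery_kwargs,
) -> dict:
    """Full inference: phage promoters + σ70 promoters + temporal report."""
    disc = discover_phage_promoters(genome, genes, **discovery_kwargs)
    sigma_preds: list[SigmaPromoterPrediction] = []
    threshold = None
    warning = None
    if sigma70_model is not None:
        sigma_preds, threshold, warning = predict_sigma70(genome, genes, sigma70_model)
    assignments = classify_genes_temporal(genome, genes, sigma_preds, disc.promoters)
    report = strategy_report(genome, assignments, sigma_preds, disc.promoters)
    report["phage_promoter_core"] = disc.core
    report["sigma70_threshold"] = threshold
    report["sigma70_warning"] = warning
    report["n_motif_sets"] = len(disc.motif_sets)
    return report
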