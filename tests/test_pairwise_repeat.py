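import numpy as np
import pytest

from strategykit.intergenic import IntergenicRegion
from strategykit.pairwise_repeat import (
    AlignScoring,
    consolidate_motifs,
    local_align,
    repeat_evalue,
    repeat_search,
)

from conftest import random_dna


def _region(seq, gene=1, start=1, strand="+", glen=10_000):
    return IntergenicRegion(
        downstream_gene=gene, upstream_gene=None, sequence=seq,
        start=start, end=start + len(seq) - 1, strand=strand,
        fused_offset=0, group="plus", genome_length=glen,
    )


class TestLocalAlign:
    def test_example_core_hit(self):
        hits = local_align("TGTGATGTTATA", "GGGGATGTTATA")
        assert hits, "expected a shared 9-mer hit"
        best = hits[0]
        assert (best.length, best.identities, best.score) == (9, 9, 9)
        assert "TGTGATGTTATA"[best.a_start : best.a_start + best.a_len] == "GATGTTATA"

    def test_empty_sequence(self):
        assert local_align("", "ACGTACGT") == []

    def test_self_comparison_excludes_diagonal(self):
        scoring = AlignScoring(min_hit_len=4)
        hits = local_align("ACGTACGT", "ACGTACGT", scoring, self_comparison=True)
        assert hits
        for h in hits:
            assert h.a_start < h.b_start  # mirror & identity hits excluded
        assert hits[0].identities == 4  # the off-diagonal ACGT repeat

    def test_determinism(self):
        rng = np.random.default_rng(0)
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        assert local_align(a, b) == local_align(a, b)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_biopython_optimum_short(self, trial):
        """Top hit score equals Biopython's local alignment optimum."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -3
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2
        rng = np.random.default_rng(1000 + trial)
        a = random_dna(rng, int(rng.integers(5, 16)))
        b = random_dna(rng, int(rng.integers(5, 16)))
        oracle = aligner.score(a, b)
        scoring = AlignScoring(min_hit_len=4)
        hits = local_align(a, b, scoring, min_score=4)
        if oracle >= 4:
            assert hits and hits[0].score == oracle
        else:
            assert not hits or hits[0].score <= oracle


class TestRepeatSearch:
    def test_anchor_mode_single_region(self):
        r = _region("ACGTACGTACGTACGT")
        hits = repeat_search([r], mode="anchor", scoring=AlignScoring(min_hit_len=4))
        assert all(h.region_a is r and h.region_b is r for h in hits)

    def test_all_pairs_counts(self):
        rng = np.random.default_rng(3)
        regions = [_region(random_dna(rng, 60), gene=i) for i in range(4)]
        hits = repeat_search(regions, mode="all_pairs")
        pairs = {(id(h.region_a), id(h.region_b)) for h in hits}
        # at most 4 self + 6 cross pairs can produce hits
        assert len(pairs) <= 10

    def test_recovers_planted_motif_instances(self):
        rng = np.random.default_rng(8)
        motif = "TGTGATGTTATA"
        bg = random_dna(rng, 800)
        positions = [50, 250, 450, 650]
        seq = list(bg)
        for p in positions:
            seq[p : p + 12] = motif
        anchor = _region("".join(seq))
        hits = repeat_search([anchor], mode="anchor")
        sets = consolidate_motifs(hits, search_space=800)
        sig = [s for s in sets if s.evalue <= 1e-3]
        assert len(sig) == 1
        s = sig[0]
        assert s.copy_number == 4
        assert motif in s.consensus or s.consensus in motif or motif[2:8] in s.consensus
        starts = sorted(inst[1] for inst in s.instances)
        for want, got in zip(positions, starts):
            assert abs(want - got) <= 2


class TestRepeatEvalue:
    def test_closed_form_k1(self):
        # E(1,1,4) = 4 * (1 - e^-1)
        assert repeat_evalue(1, 1, 4) == pytest.approx(4 * (1 - np.exp(-1)), rel=1e-12)

    def test_paper_regime_order_of_magnitude(self):
        e = repeat_evalue(4, 12, 4400)
        assert 1e-10 < e < 1e-8

    @pytest.mark.parametrize("k,L,n", [(2, 6, 10_000), (3, 8, 5_000), (4, 12, 4_400)])
    def test_monotonicity(self, k, L, n):
        assert repeat_evalue(k + 1, L, n) < repeat_evalue(k, L, n)
        assert repeat_evalue(k, L + 1, n) < repeat_evalue(k, L, n)
        assert repeat_evalue(k, L, 2 * n) > repeat_evalue(k, L, n)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            repeat_evalue(0, 6, 100)
        with pytest.raises(ValueError):
            repeat_evalue(2, 6, 3)

    def test_against_monte_carlo_word_counts(self):
        """Expected count of >=2-fold 6-mers in 10 kb vs direct simulation."""
        k, L, n, reps = 2, 6, 10_000, 300
        rng = np.random.default_rng(42)
        powers = 4 ** np.arange(L)
        counts = np.empty(reps)
        for r in range(reps):
            seq = rng.integers(0, 4, size=n)
            # word ids via sliding dot product
            ids = np.zeros(n - L + 1, dtype=np.int64)
            for j in range(L):
                ids += seq[j : n - L + 1 + j] * powers[j]
            occ = np.bincount(ids, minlength=4**L)
            counts[r] = (occ >= k).sum()
        mc_mean = counts.mean()
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(repeat_evalue(k, L, n) - mc_mean) <= 3 * se


class TestConsolidate:
    def test_unrelated_motifs_stay_disjoint(self):
        rng = np.random.default_rng(21)
        m1, m2 = "TGTGATGTTATA", "CCAATTGGCCAA"
        seq = list(random_dna(rng, 900))
        for p in (40, 240, 440):
            seq[p : p + 12] = m1
        for p in (600, 760):
            seq[p : p + 12] = m2
        anchor = _region("".join(seq))
        hits = repeat_search([anchor], mode="anchor")
        sets = consolidate_motifs(hits, search_space=900)
        consensi = [s.consensus for s in sets if s.copy_number >= 2]
        assert any(m1[2:10] in c for c in consensi)
        assert any(m2[2:10] in c for c in consensi)
        # no consensus contains both motifs
        assert not any(m1[2:10] in c and m2[2:10] in c for c in consensi)
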