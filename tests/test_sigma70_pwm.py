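import itertools

import numpy as np
import pytest

from strategykit._seq import BASES
from strategykit.genome_io import GenomeRecord
from strategykit.sigma70_pwm import (
    PromoterModel,
    TrainingPromoter,
    build_promoter_model,
    scan_genome,
    score_window,
    threshold_by_strand_bias,
    _logodds,
)
from strategykit.synthetic_fixtures import simulate_training_promoters

from conftest import random_dna

CONS = ("TTGACA", "TATAAT")


def _consensus_training(n=20, spacer=17):
    return [TrainingPromoter(CONS[0], spacer, CONS[1]) for _ in range(n)]


def _mixed_training():
    rows = []
    for sp in (16, 17, 17, 18):
        rows.extend(
            TrainingPromoter(CONS[0], sp, CONS[1]) for _ in range(3)
        )
    return rows


class TestBuildModel:
    def test_consensus_scores_zero_any_spacer_sequence(self):
        model = build_promoter_model(_consensus_training())
        rng = np.random.default_rng(1)
        for _ in range(10):
            window = CONS[0] + random_dna(rng, 17) + CONS[1]
            assert score_window(window, 17, model) == pytest.approx(0.0, abs=1e-12)

    def test_any_substitution_scores_negative(self):
        model = build_promoter_model(_consensus_training())
        spacer_seq = "A" * 17
        for pos in range(12):
            full = CONS[0] + CONS[1]
            for b in BASES:
                if b == full[pos]:
                    continue
                mut = full[:pos] + b + full[pos + 1 :]
                window = mut[:6] + spacer_seq + mut[6:]
                assert score_window(window, 17, model) < 0

    def test_spacer_score_frequency_ratio(self):
        model = build_promoter_model(_mixed_training())
        assert model.spacer_score[17] == pytest.approx(0.0)
        assert model.spacer_score[16] == pytest.approx(np.log(0.5))
        assert model.spacer_score[18] == pytest.approx(np.log(0.5))
        window = CONS[0] + "A" * 18 + CONS[1]
        assert score_window(window, 18, model) == pytest.approx(np.log(0.5))

    def test_logodds_hand_computed_toy(self):
        # 4 sequences, one column: 3 A + 1 C, pseudocount 0.5
        lo = _logodds(["A", "A", "A", "C"], 1, 0.5, np.full(4, 0.25))
        counts = np.array([3.5, 1.5, 0.5, 0.5])
        freqs = counts / 6.0
        expect = np.log(freqs / 0.25)
        expect -= expect.max()
        assert np.allclose(lo[0], expect)

    def test_requires_ten_training_promoters(self):
        with pytest.raises(ValueError, match=">= 10"):
            build_promoter_model(_consensus_training(4))

    def test_spacer_outside_support_rejected(self):
        rows = _consensus_training(12)
        rows[0] = TrainingPromoter(CONS[0], 25, CONS[1])
        with pytest.raises(ValueError, match="outside support"):
            build_promoter_model(rows)

    def test_hexamer_extremes_match_enumeration(self):
        """Column-wise min/max of brute-force hexamer scores match the
        additive decomposition; the unique maximum is the consensus."""
        model = build_promoter_model(simulate_training_promoters(100, seed=5))
        for pwm, cons in ((model.pwm_35, model.consensus_35), (model.pwm_10, model.consensus_10)):
            scores = {}
            for word in itertools.product(BASES, repeat=6):
                s = sum(pwm[i, BASES.index(c)] for i, c in enumerate(word))
                scores["".join(word)] = s
            best = max(scores, key=scores.get)
            assert best == cons
            assert scores[best] == pytest.approx(0.0, abs=1e-12)
            assert min(scores.values()) == pytest.approx(pwm.min(axis=1).sum())

    def test_parameter_recovery_mean_logodds(self):
        """Matrices rebuilt from 500 sampled promoters recover the generating
        log-odds to ~0.1 on average per entry."""
        p = 0.6
        tr = simulate_training_promoters(500, seed=12345, cons_35=(p,) * 6, cons_10=(p,) * 6)
        model = build_promoter_model(tr)

        def truth(consensus):
            M = np.array(
                [[np.log((p if b == c else (1 - p) / 3) / 0.25) for b in BASES]
                 for c in consensus]
            )
            return M - M.max(axis=1, keepdims=True)

        err = np.abs(
            np.concatenate(
                [(model.pwm_35 - truth(CONS[0])).ravel(),
                 (model.pwm_10 - truth(CONS[1])).ravel()]
            )
        )
        assert err.mean() <= 0.1


class TestScan:
    def test_single_planted_consensus(self):
        rng = np.random.default_rng(2)
        model = build_promoter_model(_consensus_training())
        bg = random_dna(rng, 500)
        prom = CONS[0] + random_dna(rng, 17) + CONS[1]
        seq = bg[:200] + prom + bg[200:]
        genome = GenomeRecord("t", seq, "linear")
        preds = scan_genome(genome, model, threshold=-1.0)
        exact = [p for p in preds if p.score == 0.0]
        assert len(exact) == 1
        p = exact[0]
        assert (p.start, p.end, p.strand) == (201, 229, "+")
        assert p.minus35 == CONS[0] and p.minus10 == CONS[1]

    def test_threshold_must_be_finite(self):
        model = build_promoter_model(_consensus_training())
        with pytest.raises(ValueError, match="finite"):
            scan_genome(GenomeRecord("t", "ACGT" * 30, "linear"), model, float("-inf"))

    def test_monotone_containment_in_threshold(self, sigma70_model):
        rng = np.random.default_rng(3)
        genome = GenomeRecord("t", random_dna(rng, 3000), "linear")
        loose = scan_genome(genome, sigma70_model, threshold=-8.0)
        tight = scan_genome(genome, sigma70_model, threshold=-5.0)
        loose_keys = {(p.start, p.strand) for p in loose}
        assert {(p.start, p.strand) for p in tight} <= loose_keys


class TestStrandBias:
    def _preds(self, minus_scores, plus_scores):
        from strategykit.sigma70_pwm import SigmaPromoterPrediction

        out = []
        for i, s in enumerate(minus_scores):
            out.append(SigmaPromoterPrediction("TTGACA", 17, "TATAAT", 100 * i + 1, 100 * i + 29, "-", s))
        for i, s in enumerate(plus_scores):
            out.append(SigmaPromoterPrediction("TTGACA", 17, "TATAAT", 100 * i + 51, 100 * i + 79, "+", s))
        return out

    def test_order_statistics_example(self):
        preds = self._preds([-1, -2, -3], [-4])
        thr, n_minus, n_plus, warn = threshold_by_strand_bias(preds, required_minus=3)
        assert -4 < thr <= -3
        assert (n_minus, n_plus) == (3, 0)
        assert warn is None

    def test_most_permissive_without_target(self):
        preds = self._preds([-1, -2, -3, -5], [-4])
        thr, n_minus, n_plus, _ = threshold_by_strand_bias(preds)
        assert (n_minus, n_plus) == (3, 0)

    def test_warning_when_plus_dominates(self):
        preds = self._preds([-5, -6], [-1])
        thr, n_minus, n_plus, warn = threshold_by_strand_bias(preds, required_minus=2)
        assert warn is not None
        assert n_plus == 0

    def test_empty_input(self):
        with pytest.raises(ValueError):
            threshold_by_strand_bias([])
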