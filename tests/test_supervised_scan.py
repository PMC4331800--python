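import numpy as np
import pytest

from strategykit.intergenic import IntergenicRegion
from strategykit.supervised_scan import (
    LogoMatrix,
    build_profile,
    classify_long_short,
    compare_specificities,
    core_scan,
    information_content,
    window_pvalue,
    window_score,
)


def _region(seq, gene=1, strand="+", start=1):
    return IntergenicRegion(
        downstream_gene=gene, upstream_gene=None, sequence=seq,
        start=start, end=start + len(seq) - 1, strand=strand,
        fused_offset=0, group="all", genome_length=100_000,
    )


class TestCoreScan:
    def test_single_window_with_flanks(self):
        r = _region("AAAGTGATGTGTAAAA")
        wins = core_scan([r])
        assert len(wins) == 1
        w = wins[0]
        assert w.window == "AGTGATGTGTAA"
        assert w.local_offset == 2
        assert w.genomic_coordinate == 3

    def test_no_core_occurrence(self):
        assert core_scan([_region("ACACACACACACACAC")]) == []

    def test_truncated_window_skipped(self):
        # core starts at offset 0: no room for the 2 bp left flank
        assert core_scan([_region("TGATGTGTAAAA")]) == []

    def test_ambiguous_window_skipped(self):
        assert core_scan([_region("AANGTGATGTGTAAAA")]) == []

    def test_sliding_window_oracle(self):
        """Every reported window agrees with a naive re-scan."""
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        r = _region(seq)
        got = {(w.local_offset, w.window) for w in core_scan([r])}
        want = set()
        for i in range(len(seq) - 5):
            if seq[i : i + 6] == "TGATGT" and i >= 2 and i + 10 <= len(seq):
                want.add((i - 2, seq[i - 2 : i + 10]))
        assert got == want


class TestClassification:
    @pytest.mark.parametrize(
        "window,expected",
        [
            ("TGTGATGTTATA", "late_long"),   # exact long motif
            ("AGTGATGTGTAA", "middle_short"),  # no TATA suffix
            ("GGGGATGTTATA", "late_long"),   # one TG mismatch but TATA present
            ("TTTGATGTAGTC", "middle_short"),
            ("CCTGATGTAACT", "middle_short"),
        ],
    )
    def test_rule(self, window, expected):
        r = _region("AA" + window + "AAAA", start=101)
        w = core_scan([r], core=window[2:8])[0]
        (m,) = classify_long_short([w])
        assert m.promoter_class == expected
        if expected == "late_long":
            assert m.genomic_coordinate == 103  # window start
        else:
            assert m.genomic_coordinate == 105  # core start

    def test_partition_is_total(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            win = "".join(rng.choice(list("ACGT"), size=12))
            r = _region("AA" + win + "AAAA")
            (m,) = classify_long_short([core_scan([r], core=win[2:8])[0]])
            assert m.promoter_class in ("late_long", "middle_short")


class TestInformationContent:
    def test_conserved_column_two_bits(self):
        logo = information_content(["T", "T", "T", "T"])
        assert logo.information[0] == pytest.approx(2.0)

    def test_uniform_column_zero_bits(self):
        logo = information_content(["A", "C", "G", "T"])
        assert logo.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_quarters_column(self):
        # 3 T + 1 G: IC = 2 - H(0.75, 0.25) = 2 - 0.8113 = 1.1887
        logo = information_content(["T", "T", "T", "G"])
        h = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert logo.information[0] == pytest.approx(2 - h)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            information_content(["ACGT", "ACG"])


class TestWindowPvalue:
    def test_uniform_profile_p_one(self):
        profile = LogoMatrix(np.full((12, 4), 0.25))
        assert window_pvalue("TGTGATGTTATA", profile) == pytest.approx(1.0)

    def test_consensus_tail_near_deterministic(self):
        seqs = ["TGTGATGTTATA"] * 40
        profile = build_profile(seqs, pseudocount=0.01)
        p = window_pvalue("TGTGATGTTATA", profile)
        assert p == pytest.approx(0.25**12, rel=0.05)

    def test_degenerate_profile_rejected(self):
        freqs = np.full((4, 4), 0.0)
        freqs[:, 0] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            window_pvalue("AAAA", LogoMatrix(freqs))

    def test_monotone_in_score_and_matches_monte_carlo(self):
        seqs = ["TGTGATGTTATA", "TGTGATGTTATA", "TGTAATGTTATA", "GGGGATGTTATA"]
        profile = build_profile(seqs)
        rng = np.random.default_rng(17)
        wins = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(20)]
        wins.append("TGTGATGTTATA")
        scored = sorted(
            ((window_score(w, profile), window_pvalue(w, profile)) for w in wins)
        )
        pv = [p for _, p in scored]
        assert all(pv[i] >= pv[i + 1] - 1e-12 for i in range(len(pv) - 1))
        # Monte-Carlo check of the exact tail for one mid-range window
        w = wins[0]
        obs = window_score(w, profile)
        llr = np.log(profile.freqs / 0.25)
        draws = rng.integers(0, 4, size=(100_000, 12))
        sims = llr[np.arange(12)[None, :], draws].sum(axis=1)
        emp = (sims >= obs - 1e-9).mean()
        se = max(np.sqrt(emp * (1 - emp) / draws.shape[0]), 1e-5)
        assert abs(emp - window_pvalue(w, profile)) <= 3 * se + 1e-3


class TestCompareSpecificities:
    def test_identical_logos(self):
        seqs = ["TGTGATGTTATA", "TGTAATGTTATA", "GGGGATGTTATA"]
        logo = information_content(seqs)
        res = compare_specificities(logo, logo)
        assert res.offset == 0 and res.gap_in is None
        assert res.aligned_columns == 12

    def test_recovers_inserted_gap(self):
        rng = np.random.default_rng(6)
        # sharp, distinct columns
        freqs = np.full((10, 4), 0.04)
        for i in range(10):
            freqs[i, rng.integers(0, 4)] = 0.88
        logo_a = LogoMatrix(freqs)
        # drop column 4: aligning back requires one gap in b at position 4
        logo_b = LogoMatrix(np.vstack([freqs[:4], freqs[5:]]))
        res = compare_specificities(logo_a, logo_b)
        assert res.gap_in == "b"
        assert res.gap_position == 4
        assert res.offset == 0

    def test_phiEco32_like_consensus_needs_one_gap(self):
        """The long-motif logo vs a TAATGTATA-consensus logo aligns with
        exactly one gap, mirroring the cross-phage specificity comparison."""
        long_motifs = ["TGTGATGTTATA", "TGTGATGTTATA", "TGTAATGTTATA", "GGGGATGTTATA"]
        logo_711 = information_content(long_motifs)
        logo_32 = information_content(["TAATGTATA"])
        res = compare_specificities(logo_711, logo_32)
        assert res.gap_in is not None
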