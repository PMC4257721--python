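import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgepair import stats
from dgepair.io import GeneCount, LibraryPair
from dgepair.stats import TestConfig as Config

from oracles import bh_brute, frac_audic_lower, frac_audic_pmf, frac_audic_pvalue

N = 1_000_000


class TestRpkm:
    def test_units_cancel(self):
        assert stats.compute_rpkm(1000, 1000, 1_000_000_000) == 1.0

    def test_zero_count(self):
        assert stats.compute_rpkm(0, 500, 1_000_000) == 0.0

    def test_published_row_matches_exact_rational(self):
        # oracle: exact rational evaluation of 1e9 * 18 / (688 * 25603968)
        expected = Fraction(10**9) * 18 / (688 * 25_603_968)
        value = stats.compute_rpkm(18, 688, 25_603_968)
        assert value == pytest.approx(float(expected), rel=1e-12)
        assert 1.0218 < value < 1.0219

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            stats.compute_rpkm(5, 0, 1000)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            stats.compute_rpkm(5, 100, 0)


class TestLog2FoldChange:
    def test_simple_doubling(self):
        assert stats.log2_fold_change(1.0, 2.0) == 1.0

    @pytest.mark.parametrize("a", [0.3, 1.0, 57.2])
    def test_identity(self, a):
        assert stats.log2_fold_change(a, a) == 0.0

    def test_zero_substitution(self):
        # 5.12 / 0.01 = 512 = 2**9
        assert stats.log2_fold_change(0.0, 5.12, 0.01) == pytest.approx(9.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            stats.log2_fold_change(-1.0, 2.0)

    @given(
        count_l=st.integers(0, 10_000),
        count_s=st.integers(0, 10_000),
        length=st.integers(100, 5000),
        factor=st.integers(2, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, count_l, count_s, length, factor):
        # multiplying both counts and both totals by one factor leaves the
        # ratio unchanged
        l1 = stats.compute_rpkm(count_l, length, N)
        s1 = stats.compute_rpkm(count_s, length, N)
        l2 = stats.compute_rpkm(count_l * factor, length, N * factor)
        s2 = stats.compute_rpkm(count_s * factor, length, N * factor)
        a = stats.log2_fold_change(l1, s1)
        b = stats.log2_fold_change(l2, s2)
        if count_l > 0 and count_s > 0:
            assert a == pytest.approx(b, abs=1e-12)


class TestAudicPmf:
    def test_zero_zero_equal_totals(self):
        assert stats.audic_pmf(0, 0, N, N) == pytest.approx(0.5, rel=1e-12)

    def test_zero_three_equal_totals(self):
        # reduces to (1/2)**(y+1)
        assert stats.audic_pmf(0, 3, N, N) == pytest.approx(0.0625, rel=1e-12)

    def test_against_exact_rational(self):
        expected = float(frac_audic_pmf(5, 12, 1_000_000, 3_000_000))
        assert stats.audic_pmf(5, 12, 1_000_000, 3_000_000) == pytest.approx(
            expected, rel=1e-12
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            stats.audic_pmf(-1, 2, N, N)

    def test_swap_identity_exact(self):
        # p(x | y; N2, N1) == (N2/N1) * p(y | x; N1, N2), an exact identity
        for x, y in [(0, 0), (3, 8), (20, 5)]:
            for n1, n2 in [(N, N), (N, 3 * N), (5 * N, N)]:
                assert stats.audic_pmf(y, x, n2, n1) == pytest.approx(
                    (n2 / n1) * stats.audic_pmf(x, y, n1, n2), rel=1e-10
                )


class TestAudicPvalue:
    @pytest.mark.parametrize("x", [0, 1, 5, 20])
    def test_equal_counts_equal_totals_give_one(self, x):
        # lower tail is exactly 0.5 when r=1 and y=x; doubling and capping -> 1
        assert frac_audic_lower(x, x, N, N) == Fraction(1, 2)
        assert stats.audic_pvalue(x, x, N, N) == pytest.approx(1.0, abs=1e-12)

    def test_zero_zero_unequal_totals(self):
        assert stats.audic_pvalue(0, 0, N, 2 * N) == pytest.approx(2 / 3, rel=1e-12)
        assert frac_audic_pvalue(0, 0, N, 2 * N) == Fraction(2, 3)

    def test_against_brute_force_tails(self):
        expected = float(frac_audic_pvalue(3, 30, 1_000_000, 1_000_000))
        assert stats.audic_pvalue(3, 30, 1_000_000, 1_000_000) == pytest.approx(
            expected, rel=1e-10
        )

    def test_in_unit_interval(self):
        # mathematically in (0, 1]; extreme tails may underflow to 0.0 in
        # double precision
        grid = [(0, 0), (0, 50), (50, 0), (10, 10), (1000, 3)]
        for x, y in grid:
            p = stats.audic_pvalue(x, y, N, 3 * N)
            assert 0.0 <= p <= 1.0
        assert stats.audic_pvalue(10, 10, N, 3 * N) > 0.0

    @given(
        x=st.integers(0, 200),
        y=st.integers(0, 200),
        n1=st.integers(10**5, 10**8),
        n2=st.integers(10**5, 10**8),
    )
    @settings(max_examples=200, deadline=None)
    def test_tail_complement_identity(self, x, y, n1, n2):
        # P(Y <= y | x; N1, N2) + P(X <= x | y; N2, N1) == 1 exactly;
        # this is the exact exchange property of the construction
        total = stats.audic_lower_tail(x, y, n1, n2) + stats.audic_lower_tail(
            y, x, n2, n1
        )
        assert total == pytest.approx(1.0, abs=1e-9)


class TestBhFdr:
    def test_single(self):
        assert stats.bh_fdr([0.37]) == pytest.approx([0.37])

    def test_hand_worked(self):
        # 0.04*4/4=0.04; 0.03*4/3=0.04; 0.02*4/2=0.04; 0.01*4/1=0.04
        assert stats.bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert stats.bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=150, deadline=None)
    def test_matches_brute_force(self, ps):
        assert stats.bh_fdr(ps) == pytest.approx(bh_brute(ps), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_never_decreases(self, ps):
        q = stats.bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)

    def test_monotone(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=100)
        q = stats.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestCallDegs:
    def test_thresholds(self, small_counts, small_libs):
        records = stats.call_degs(small_counts, small_libs)
        by_id = {r.gene_id: r for r in records}
        assert "gE" not in by_id  # untestable, dropped
        assert len(records) == 4
        assert by_id["gA"].direction == "up"
        assert by_id["gA"].is_deg  # 100 vs 400 at equal totals is extreme
        assert by_id["gC"].direction == "down"
        assert by_id["gC"].is_deg
        assert not by_id["gB"].is_deg  # 50 vs 55: neither criterion met

    def test_invariants(self, small_counts, small_libs):
        config = Config()
        for r in stats.call_degs(small_counts, small_libs, config):
            assert r.fdr >= r.p_value - 1e-15
            assert r.is_deg == (
                r.fdr <= config.fdr_threshold and abs(r.log2_ratio) >= config.min_abs_log2
            )
            if r.log2_ratio > 0:
                assert r.direction == "up"
            elif r.log2_ratio < 0:
                assert r.direction == "down"
            else:
                assert r.direction == "none"

    def test_is_deg_rule_inclusive_boundaries(self):
        config = Config()
        assert stats.is_deg(1.2, 0.0005, config)
        assert not stats.is_deg(0.5, 0.0005, config)
        assert stats.is_deg(-1.0, 1e-5, config)  # both thresholds inclusive
        assert stats.is_deg(1.0, 0.001, config)
        assert not stats.is_deg(1.0, 0.0011, config)

    def test_zero_substitution_path(self, small_libs):
        counts = [GeneCount("g", 1000, 0, 40), GeneCount("h", 1000, 10, 10)]
        records = stats.call_degs(counts, small_libs)
        g = records[0]
        assert g.rpkm_L == 0.0
        assert math.isfinite(g.log2_ratio) and g.log2_ratio > 0

    def test_empty_rejected(self, small_libs):
        with pytest.raises(ValueError):
            stats.call_degs([], small_libs)

    def test_summary(self, small_counts, small_libs):
        records = stats.call_degs(small_counts, small_libs)
        summary = stats.summarize_degs(records)
        assert summary["genes_tested"] == 4
        assert summary["degs_up"] + summary["degs_down"] == summary["degs_total"]
        assert summary["degs_total"] <= summary["genes_tested"]


class TestConfigValidation:
    def test_defaults(self):
        config = Config()
        assert config.fdr_threshold == 0.001
        assert config.min_abs_log2 == 1.0
        assert config.zero_substitute == 0.01
        assert config.rpkm_scale == 1e9

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fdr_threshold": 0.0},
            {"min_abs_log2": -1.0},
            {"zero_substitute": 0.0},
        ],
    )
    def test_nonpositive_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Config(**kwargs)
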