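"""Unit and property tests for the small-sample statistics toolbox.

Every exact test is cross-checked against an independent brute-force
oracle implemented here with nothing but ``math.comb``/``itertools``.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from degcord.stats import (
    ContingencyTable2x2,
    binomial_sign_test,
    chi2_2x2,
    correlation_suite,
    fisher_exact_2x2,
    fisher_z_correlation,
    goodman_kruskal_gamma,
    mann_whitney_u,
    z_test_two_sample,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def fisher_oracle_one_sided(a: int, b: int, c: int, d: int) -> float:
    """Hypergeometric tail in the direction of the observed association."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)

    def pmf(k: int) -> float:
        return math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)

    ks = range(a, hi + 1) if a * d >= b * c else range(lo, a + 1)
    return sum(pmf(k) for k in ks)


def binomial_oracle_upper(k: int, n: int, p0: float = 0.5) -> float:
    return sum(math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))


def mann_whitney_oracle_two_sided(x, y) -> float:
    """Exhaustive relabeling null: doubled smaller tail of U (point included)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(first):
        rest = [v for i, v in enumerate(pooled) if i not in set(first)]
        xs = [pooled[i] for i in first]
        return sum(1 for a in xs for b in rest if a > b) + 0.5 * sum(
            1 for a in xs for b in rest if a == b
        )

    u_obs = u_stat(range(n1))
    us = [u_stat(comb) for comb in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(u <= u_obs for u in us) / len(us)
    hi = sum(u >= u_obs for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


class TestFisherExact:
    def test_frozen_table_7_0_2_5(self):
        # oracle: only a=7 is at least as extreme; C(9,7)/C(14,7) = 36/3432
        res = fisher_exact_2x2(ContingencyTable2x2(7, 0, 2, 5), sided="one")
        assert res.p_value == pytest.approx(36 / 3432, rel=1e-12)
        assert res.p_value == pytest.approx(0.01049, abs=5e-6)

    def test_degenerate_diagonal(self):
        res = fisher_exact_2x2(ContingencyTable2x2(1, 0, 0, 1), sided="one")
        assert res.p_value == pytest.approx(0.5)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(ContingencyTable2x2(0, 0, 0, 0))

    @given(
        st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d), sided="one")
        assert res.p_value == pytest.approx(fisher_oracle_one_sided(a, b, c, d), rel=1e-9)

    def test_two_sided_at_least_one_sided(self):
        t = ContingencyTable2x2(7, 0, 2, 5)
        assert (
            fisher_exact_2x2(t, sided="two").p_value
            >= fisher_exact_2x2(t, sided="one").p_value
        )


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


class TestChi2:
    @pytest.mark.parametrize(
        "counts,expected",
        [((7, 0, 2, 5), 7.78), ((13, 1, 7, 7), 6.30)],
    )
    def test_uncorrected_reference_values(self, counts, expected):
        res = chi2_2x2(ContingencyTable2x2(*counts), continuity_correction=False)
        assert round(res.statistic, 2) == expected

    def test_balanced_table_is_zero(self):
        res = chi2_2x2(ContingencyTable2x2(5, 5, 5, 5))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_scipy_contingency(self):
        from scipy.stats import chi2_contingency

        rng = np.random.default_rng(7)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 20, size=4)
            mine = chi2_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            ref = chi2_contingency([[a, b], [c, d]], correction=False)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-12)
            assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_yates_correction_shrinks_statistic(self):
        t = ContingencyTable2x2(7, 0, 2, 5)
        assert chi2_2x2(t, True).statistic < chi2_2x2(t, False).statistic

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(ContingencyTable2x2(3, 0, 4, 0))


# ---------------------------------------------------------------------------
# binomial sign test
# ---------------------------------------------------------------------------


class TestBinomialSignTest:
    def test_5_of_7(self):
        assert binomial_sign_test(5, 7).p_value == pytest.approx(29 / 128)
        assert round(binomial_sign_test(5, 7).p_value, 2) == 0.23

    def test_7_of_7(self):
        assert binomial_sign_test(7, 7).p_value == pytest.approx(1 / 128)

    def test_13_of_14(self):
        assert binomial_sign_test(13, 14).p_value == pytest.approx(15 / 16384)

    def test_upper_tail_from_zero_is_one(self):
        assert binomial_sign_test(0, 10).p_value == 1.0

    @given(st.integers(1, 60), st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_pmf_summation(self, n, data):
        k = data.draw(st.integers(0, n))
        res = binomial_sign_test(k, n)
        assert res.p_value == pytest.approx(binomial_oracle_upper(k, n), rel=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_sign_test(5, 4)
        with pytest.raises(ValueError):
            binomial_sign_test(-1, 4)


# ---------------------------------------------------------------------------
# correlation suite
# ---------------------------------------------------------------------------


class TestCorrelationSuite:
    def test_monotone_transform_gives_unit_rank_correlations(self):
        x = np.arange(1.0, 11.0)
        suite = correlation_suite(x, x**2)
        assert suite.rho == pytest.approx(1.0)
        assert suite.tau == pytest.approx(1.0)
        assert suite.gamma == pytest.approx(1.0)
        assert suite.r < 1.0

    def test_perfect_discordance(self):
        suite = correlation_suite([1, 2, 3], [3, 2, 1])
        assert suite.r == pytest.approx(-1.0)
        assert suite.gamma == pytest.approx(-1.0)

    def test_six_point_platform_style_agreement(self):
        # three strong effects plus three near-zero reference points with
        # identical orderings on both axes
        x = [1.87, 3.99, 6.02, 0.02, 0.05, 0.08]
        y = [1.85, 2.95, 7.06, 0.01, 0.03, 0.06]
        suite = correlation_suite(x, y)
        assert suite.gamma == pytest.approx(1.0)
        assert suite.rho == pytest.approx(1.0)
        assert suite.p_gamma < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlation_suite([1.0, 1.0, 1.0], [1, 2, 3])

    def test_gamma_all_ties_rejected(self):
        with pytest.raises(ValueError):
            goodman_kruskal_gamma([1, 1, 1], [2, 2, 2])

    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=25),
        st.data(),
    )
    @settings(max_examples=150, deadline=None)
    def test_tau_bounded_by_gamma(self, x, data):
        y = data.draw(
            st.lists(st.floats(-50, 50), min_size=len(x), max_size=len(x))
        )
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        try:
            suite = correlation_suite(x, y)
        except ValueError:
            return
        assert abs(suite.tau) <= abs(suite.gamma) + 1e-12


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


class TestMannWhitney:
    def test_complete_separation_8v8(self, table5_samples):
        aggressive = [s.rel_expr for s in table5_samples[("Ascl3", "aggressive")]]
        tame = [s.rel_expr for s in table5_samples[("Ascl3", "tame")]]
        assert max(aggressive) < min(tame)
        res = mann_whitney_u(aggressive, tame)
        assert res.method == "mann_whitney_exact"
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2 / math.comb(16, 8), rel=1e-12)

    def test_identical_samples(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(4.5)

    def test_constant_pooled_data(self):
        res = mann_whitney_u([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4).round(3)
        y = rng.normal(1.0, size=5).round(3)
        res = mann_whitney_u(x, y)
        assert res.method == "mann_whitney_exact"
        assert res.p_value == pytest.approx(
            mann_whitney_oracle_two_sided(x, y), rel=1e-9
        )

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(0)
        res = mann_whitney_u(rng.normal(size=30), rng.normal(size=30))
        assert res.method == "mann_whitney_normal_tie_corrected"

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# z tests
# ---------------------------------------------------------------------------


class TestZTests:
    def test_equal_means(self):
        res = z_test_two_sample(1.0, 0.1, 1.0, 0.1)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_borderline_quantile(self):
        res = z_test_two_sample(1.96, 1 / math.sqrt(2), 0.0, 1 / math.sqrt(2))
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_ascl3_group_summaries_significant(self):
        res = z_test_two_sample(2.0375, 0.2138, 0.26375, 0.1120)
        assert abs(res.statistic) > 7
        assert res.p_value < 0.05

    def test_nonpositive_sem_rejected(self):
        with pytest.raises(ValueError):
            z_test_two_sample(1.0, 0.0, 2.0, 0.1)

    def test_fisher_z_correlation(self):
        res = fisher_z_correlation(0.89, 6)
        assert res.p_value < 0.05
        with pytest.raises(ValueError):
            fisher_z_correlation(1.0, 10)


def test_type_i_error_of_sign_test_under_null():
    """One-sided majority test at alpha=0.05 rejects <= 6% of null draws."""
    from scipy.stats import binom

    rng = np.random.default_rng(42)
    n_pairs, reps = 20, 10_000
    k = rng.binomial(n_pairs, 0.5, size=reps)
    majority = np.maximum(k, n_pairs - k)
    p = binom.sf(majority - 1, n_pairs, 0.5)
    assert (p < 0.05).mean() <= 0.06
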