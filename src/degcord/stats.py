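"""Exact and classical small-sample statistics.

Conventions baked in here (and echoed in every :class:`TestResult`):

* Pearson chi-square on 2x2 tables is computed WITHOUT the Yates
  continuity correction by default.
* Fisher's exact test defaults to one-sided in the direction of the
  observed association.
* The binomial sign test is one-sided in the majority direction, with the
  upper tail including the observed count.
* Kendall's tau is tau-b; the Goodman-Kruskal gamma excludes all tied
  pairs from its denominator.
* "Z-test" on two group summaries is the two-sample comparison of means
  scaled by their standard errors; the r-to-z transform for correlations
  is a separate helper (:func:`fisher_z_correlation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "CorrelationSuite",
    "fisher_exact_2x2",
    "chi2_2x2",
    "binomial_sign_test",
    "correlation_suite",
    "goodman_kruskal_gamma",
    "mann_whitney_u",
    "z_test_two_sample",
    "fisher_z_correlation",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def margins(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.a + self.b, self.c + self.d), (self.a + self.c, self.b + self.d)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sided: str  # "one" | "two"
    method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        if not math.isfinite(self.statistic):
            raise ValueError("statistic must be finite")

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "sided": self.sided,
            "method": self.method,
        }


@dataclass(frozen=True)
class CorrelationSuite:
    r: float
    rho: float
    tau: float
    gamma: float
    p_r: float
    p_rho: float
    p_tau: float
    p_gamma: float
    n: int

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def fisher_exact_2x2(t: ContingencyTable2x2, sided: str = "one") -> TestResult:
    """Exact hypergeometric test with fixed margins.

    One-sided: tail probability of the top-left cell being at least as
    extreme as observed, in the direction of the observed association.
    Two-sided: sum over tables no more probable than the observed one.
    """
    if t.n == 0:
        raise ValueError("cannot test an all-zero table")
    table = t.as_array()
    if sided == "one":
        # direction of the observed association: enrichment of cell a when
        # the odds ratio exceeds 1, depletion otherwise
        alternative = "greater" if t.a * t.d >= t.b * t.c else "less"
        res = sps.fisher_exact(table, alternative=alternative)
        # statistic is the observed top-left count: the odds ratio is
        # infinite whenever b or c is zero
        return TestResult(statistic=float(t.a), p_value=float(res.pvalue),
                          sided="one", method="fisher_exact")
    res = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(statistic=float(t.a), p_value=float(res.pvalue),
                      sided="two", method="fisher_exact")


def chi2_2x2(t: ContingencyTable2x2, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (1 df), uncorrected by default."""
    if t.n == 0:
        raise ValueError("cannot test an all-zero table")
    (r1, r2), (c1, c2) = t.margins
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: an expected count is zero")
    obs = t.as_array().astype(float)
    expected = np.outer([r1, r2], [c1, c2]) / t.n
    diff = np.abs(obs - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return TestResult(
        statistic=chi2,
        p_value=max(p, np.nextafter(0, 1)),
        sided="two",
        method="chi2_yates" if continuity_correction else "chi2_uncorrected",
    )


def binomial_sign_test(k: int, n: int, p0: float = 0.5, sided: str = "one") -> TestResult:
    """Exact binomial tail probability for k successes in n trials.

    One-sided returns the upper-tail P(X >= k) including the observed
    count; callers testing a majority direction should pass the majority
    count as ``k``.
    """
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"invalid k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    if sided == "one":
        p = float(sps.binom.sf(k - 1, n, p0))
        return TestResult(statistic=float(k), p_value=min(p, 1.0), sided="one",
                          method="binomial_upper_tail")
    res = sps.binomtest(k, n, p0, alternative="two-sided")
    return TestResult(statistic=float(k), p_value=float(res.pvalue), sided="two",
                      method="binomial_two_sided")


def goodman_kruskal_gamma(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Gamma = (C - D) / (C + D) over untied pairs, with its asymptotic-z p.

    The normal approximation z = gamma * sqrt((C + D) / (n (1 - gamma^2)))
    is the textbook large-sample form. It degenerates at |gamma| = 1, where
    the exact null probability of a perfectly concordant (or discordant)
    arrangement, 2/n!, is reported instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    prod = dx * dy
    iu = np.triu_indices(n, k=1)
    concordant = int((prod[iu] > 0).sum())
    discordant = int((prod[iu] < 0).sum())
    if concordant + discordant == 0:
        raise ValueError("gamma undefined: all pairs tied")
    gamma = (concordant - discordant) / (concordant + discordant)
    if abs(gamma) >= 1.0:
        p = min(1.0, 2 / math.factorial(n))
    else:
        z = gamma * math.sqrt((concordant + discordant) / (n * (1 - gamma**2)))
        p = max(float(2 * sps.norm.sf(abs(z))), np.nextafter(0, 1))
    return float(gamma), p


def correlation_suite(x: Sequence[float], y: Sequence[float]) -> CorrelationSuite:
    """Pearson r, Spearman rho, Kendall tau-b and Goodman-Kruskal gamma."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for the correlation suite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    r_res = sps.pearsonr(x, y)
    rho_res = sps.spearmanr(x, y)
    tau_res = sps.kendalltau(x, y)  # tau-b
    gamma, p_gamma = goodman_kruskal_gamma(x, y)
    return CorrelationSuite(
        r=float(r_res.statistic),
        rho=float(rho_res.statistic),
        tau=float(tau_res.statistic),
        gamma=gamma,
        p_r=float(r_res.pvalue),
        p_rho=float(rho_res.pvalue),
        p_tau=float(tau_res.pvalue),
        p_gamma=p_gamma,
        n=n,
    )


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_threshold: int = 10) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation null when both samples have at most
    ``exact_threshold`` observations and there are no cross-group ties;
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return TestResult(statistic=len(x) * len(y) / 2, p_value=1.0, sided="two",
                          method="mann_whitney_degenerate")
    cross_ties = bool(np.intersect1d(x, y).size)
    exact = len(x) <= exact_threshold and len(y) <= exact_threshold and not cross_ties
    res = sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=False,
                           method="exact" if exact else "asymptotic")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sided="two",
        method="mann_whitney_exact" if exact else "mann_whitney_normal_tie_corrected",
    )


def z_test_two_sample(mean1: float, sem1: float, mean2: float, sem2: float) -> TestResult:
    """Two-sample z comparison of group means scaled by their SEMs."""
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    z = (mean1 - mean2) / math.hypot(sem1, sem2)
    p = max(float(2 * sps.norm.sf(abs(z))), np.nextafter(0, 1))
    return TestResult(statistic=z, p_value=min(p, 1.0), sided="two", method="z_two_sample")


def fisher_z_correlation(r: float, n: int) -> TestResult:
    """Significance of a correlation via the r-to-z (atanh) transform."""
    if not (-1.0 < r < 1.0):
        raise ValueError("r must be strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z = math.atanh(r) * math.sqrt(n - 3)
    p = max(float(2 * sps.norm.sf(abs(z))), np.nextafter(0, 1))
    return TestResult(statistic=z, p_value=min(p, 1.0), sided="two",
                      method="fisher_z_correlation")
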