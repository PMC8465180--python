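"""qPCR verification statistics: group aggregation and cross-platform checks.

Relative expression values are consumed as given (per-animal means against
reference genes); Ct-level processing is upstream and out of scope.

ND (below detection) handling is policy-driven: ``exclude`` drops the
animal, ``impute`` substitutes the detection limit. The default pairing —
exclude for means, impute for hypothesis tests — keeps the printed group
means reproducible while letting rank tests run on full groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

from .stats import CorrelationSuite, TestResult, correlation_suite, mann_whitney_u, z_test_two_sample

__all__ = [
    "QPCRSample",
    "QPCRGroupSummary",
    "DEGVerification",
    "aggregate_group",
    "group_log2_ratio",
    "verify_deg",
    "crossplatform_correlation",
    "DETECTION_LIMIT",
]

DETECTION_LIMIT = 0.01


@dataclass(frozen=True)
class QPCRSample:
    gene: str
    animal_id: int
    group: str
    behavior_score: int
    rel_expr: float | None  # None == below detection
    nd_flag: bool = False

    def __post_init__(self) -> None:
        if not (-4 <= self.behavior_score <= 4):
            raise ValueError("behavior_score must be in [-4, 4]")
        if not self.nd_flag and (self.rel_expr is None or self.rel_expr < 0):
            raise ValueError("rel_expr must be >= 0 unless flagged ND")


@dataclass(frozen=True)
class QPCRGroupSummary:
    gene: str
    group: str
    m0: float
    sem: float
    n_used: int
    n_nd: int


@dataclass(frozen=True)
class DEGVerification:
    gene: str
    high: QPCRGroupSummary
    low: QPCRGroupSummary
    mann_whitney: TestResult
    z_test: TestResult
    qpcr_log2: float
    rnaseq_log2: float
    sign_agreement: bool
    alpha: float

    @property
    def significant_both(self) -> bool:
        return self.mann_whitney.p_value < self.alpha and self.z_test.p_value < self.alpha

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "qpcr_log2": self.qpcr_log2,
            "rnaseq_log2": self.rnaseq_log2,
            "sign_agreement": self.sign_agreement,
            "mann_whitney": self.mann_whitney.to_dict(),
            "z_test": self.z_test.to_dict(),
            "significant_both": self.significant_both,
            "alpha": self.alpha,
        }


def _group_values(samples: Sequence[QPCRSample], nd_policy: str,
                  detection_limit: float) -> tuple[list[float], int]:
    values, n_nd = [], 0
    for s in samples:
        if s.nd_flag or s.rel_expr is None:
            n_nd += 1
            if nd_policy == "impute":
                values.append(detection_limit)
        else:
            values.append(s.rel_expr)
    return values, n_nd


def aggregate_group(samples: Sequence[QPCRSample], nd_policy: str = "exclude",
                    detection_limit: float = DETECTION_LIMIT) -> QPCRGroupSummary:
    """Arithmetic mean and SEM (n-1 sd / sqrt(n)) over per-animal values."""
    if nd_policy not in ("exclude", "impute"):
        raise ValueError(f"unknown nd_policy {nd_policy!r}")
    genes = {s.gene for s in samples}
    groups = {s.group for s in samples}
    if len(genes) != 1 or len(groups) != 1:
        raise ValueError("samples must share one gene and one group")
    values, n_nd = _group_values(samples, nd_policy, detection_limit)
    if not values:
        raise ValueError("no animals left after ND handling")
    m0 = mean(values)
    sem = (stdev(values) / math.sqrt(len(values))) if len(values) > 1 else 0.0
    return QPCRGroupSummary(gene=genes.pop(), group=groups.pop(), m0=m0, sem=sem,
                            n_used=len(values), n_nd=n_nd)


def group_log2_ratio(high: QPCRGroupSummary, low: QPCRGroupSummary) -> float:
    """log2 of the ratio of the two group means (numerator = ``high``)."""
    if high.m0 <= 0 or low.m0 <= 0:
        raise ValueError("group means must be positive for a log2 ratio")
    return math.log2(high.m0 / low.m0)


def verify_deg(samples: Sequence[QPCRSample], rnaseq_log2: float, *,
               high_group: str = "tame", low_group: str = "aggressive",
               alpha: float = 0.05,
               nd_policy_tests: str = "impute",
               nd_policy_means: str = "exclude",
               detection_limit: float = DETECTION_LIMIT) -> DEGVerification:
    """Cross-check one gene's qPCR groups against its RNA-Seq log2 value."""
    genes = {s.gene for s in samples}
    if len(genes) != 1:
        raise ValueError("verify_deg expects samples of a single gene")
    high = [s for s in samples if s.group == high_group]
    low = [s for s in samples if s.group == low_group]
    if not high or not low:
        raise ValueError("both groups must be present")
    high_vals, _ = _group_values(high, nd_policy_tests, detection_limit)
    low_vals, _ = _group_values(low, nd_policy_tests, detection_limit)
    mw = mann_whitney_u(high_vals, low_vals)
    hs = aggregate_group(high, nd_policy_tests, detection_limit)
    ls = aggregate_group(low, nd_policy_tests, detection_limit)
    z = z_test_two_sample(hs.m0, max(hs.sem, 1e-12), ls.m0, max(ls.sem, 1e-12))
    hs_mean = aggregate_group(high, nd_policy_means, detection_limit)
    ls_mean = aggregate_group(low, nd_policy_means, detection_limit)
    qpcr_log2 = group_log2_ratio(hs_mean, ls_mean)
    sign_agreement = qpcr_log2 * rnaseq_log2 > 0 or (qpcr_log2 == rnaseq_log2 == 0)
    return DEGVerification(
        gene=genes.pop(), high=hs_mean, low=ls_mean, mann_whitney=mw, z_test=z,
        qpcr_log2=qpcr_log2, rnaseq_log2=rnaseq_log2,
        sign_agreement=sign_agreement, alpha=alpha,
    )


def crossplatform_correlation(points: Sequence[tuple[float, float]]) -> dict:
    """Correlation suite + linear fit of platform-paired log2 values.

    ``points`` are (log2 from sequencing, log2 from qPCR). Returns the
    suite, the least-squares slope/intercept, and the half-width of the
    95% confidence band of the fitted mean at each x.
    """
    import numpy as np
    from scipy import stats as sps

    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    suite = correlation_suite(x, y)
    n = len(x)
    fit = sps.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    dof = n - 2
    s2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    sxx = float(((x - x.mean()) ** 2).sum())
    tcrit = float(sps.t.ppf(0.975, dof)) if dof > 0 else float("nan")
    half_widths = tcrit * np.sqrt(s2 * (1 / n + (x - x.mean()) ** 2 / sxx))
    return {
        "suite": suite,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "ci95_half_widths": half_widths.tolist(),
    }
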