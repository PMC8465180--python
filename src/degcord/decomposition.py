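"""Two-variable PCA of paired log2 fold changes and sign-concordance tests.

For two standardized variables the eigenvalues of the correlation matrix
are 1 + |r| and 1 - |r|, so the PC1 variance fraction has the closed form
(1 + |r|) / 2; :func:`pca2` in correlation mode must agree with
:func:`pc1_fraction_closed_form` to machine precision, which the test
suite uses as an analytic oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .homology import HomologPair, MultiplicityClass, Relation, normalize_symbol
from .stats import (
    ContingencyTable2x2,
    CorrelationSuite,
    TestResult,
    binomial_sign_test,
    chi2_2x2,
    correlation_suite,
    fisher_exact_2x2,
)

__all__ = [
    "PCAResult",
    "ConcordanceResult",
    "pca2",
    "pc1_fraction_closed_form",
    "concordance_analysis",
    "stratified_correlations",
]


@dataclass(frozen=True)
class PCAResult:
    var_fraction_pc1: float
    var_fraction_pc2: float
    loadings: np.ndarray  # columns = PC1, PC2; orthonormal
    mode: str  # "correlation" | "covariance"
    n: int

    def to_dict(self) -> dict:
        return {
            "var_fraction_pc1": self.var_fraction_pc1,
            "var_fraction_pc2": self.var_fraction_pc2,
            "loadings": self.loadings.tolist(),
            "mode": self.mode,
            "n": self.n,
        }


@dataclass(frozen=True)
class ConcordanceResult:
    table: ContingencyTable2x2
    fisher: TestResult
    chi2: TestResult | None
    binomial_multi: TestResult
    binomial_single: TestResult

    def to_dict(self) -> dict:
        return {
            "table": {
                "a": self.table.a, "b": self.table.b,
                "c": self.table.c, "d": self.table.d,
                "row_labels": list(self.table.row_labels),
                "col_labels": list(self.table.col_labels),
            },
            "fisher": self.fisher.to_dict(),
            "chi2": self.chi2.to_dict() if self.chi2 else None,
            "binomial_multi": self.binomial_multi.to_dict(),
            "binomial_single": self.binomial_single.to_dict(),
        }


def _as_xy(pairs: Iterable) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    for p in pairs:
        if isinstance(p, HomologPair):
            rows.append((p.focal.log2fc, p.comparison.log2fc))
        else:
            rows.append((float(p[0]), float(p[1])))
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def pca2(pairs: Sequence, mode: str = "correlation") -> PCAResult:
    """Eigen-decomposition of the 2x2 correlation or covariance matrix.

    Variance fractions are eigenvalues over the trace; PC1 is the
    larger-eigenvalue axis with its loading on the first (focal)
    coordinate fixed non-negative.
    """
    x, y = _as_xy(pairs)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if mode == "correlation":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("constant coordinate: correlation mode undefined")
        mat = np.corrcoef(x, y)
    elif mode == "covariance":
        mat = np.cov(x, y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    eigvals, eigvecs = np.linalg.eigh(mat)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    for j in range(2):  # sign convention: focal loading >= 0
        if eigvecs[0, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    fractions = eigvals / eigvals.sum()
    return PCAResult(
        var_fraction_pc1=float(fractions[0]),
        var_fraction_pc2=float(fractions[1]),
        loadings=eigvecs,
        mode=mode,
        n=n,
    )


def pc1_fraction_closed_form(r: float) -> float:
    """PC1 variance fraction of two standardized variables: (1 + |r|) / 2."""
    if abs(r) > 1:
        raise ValueError("|r| must not exceed 1")
    return (1 + abs(r)) / 2


def concordance_analysis(classified_pairs: Sequence[HomologPair]) -> ConcordanceResult:
    """Build and test the multiplicity-class x sign-concordance 2x2 table.

    Only ORTHOLOG_MULTI and ORTHOLOG_SINGLE pairs enter the table (row 1 =
    multi, row 2 = single; column 1 = same sign, column 2 = opposite
    sign). Pairs with a zero log2fc have no sign and are dropped with a
    warning. Runs one-sided Fisher exact, uncorrected chi-square (omitted
    if a margin is zero) and a per-row upper-tail binomial sign test on
    the majority direction.
    """
    counts = {"multi_same": 0, "multi_opp": 0, "single_same": 0, "single_opp": 0}
    for p in classified_pairs:
        if p.multiplicity_class not in (
            MultiplicityClass.ORTHOLOG_MULTI,
            MultiplicityClass.ORTHOLOG_SINGLE,
        ):
            continue
        if p.focal.log2fc == 0 or p.comparison.log2fc == 0:
            warnings.warn(
                f"pair {p.pair_id} has a zero log2fc; excluded from sign counts",
                stacklevel=2,
            )
            continue
        multi = p.multiplicity_class is MultiplicityClass.ORTHOLOG_MULTI
        same = p.sign_concordant
        counts[("multi_" if multi else "single_") + ("same" if same else "opp")] += 1
    table = ContingencyTable2x2(
        a=counts["multi_same"], b=counts["multi_opp"],
        c=counts["single_same"], d=counts["single_opp"],
        row_labels=("ORTHOLOG_MULTI", "ORTHOLOG_SINGLE"),
        col_labels=("same_sign", "opposite_sign"),
    )
    if table.n == 0:
        raise ValueError("no orthologous pairs to analyze")
    fisher = fisher_exact_2x2(table, sided="one")
    try:
        chi2 = chi2_2x2(table, continuity_correction=False)
    except ValueError:
        chi2 = None
    n_multi = table.a + table.b
    n_single = table.c + table.d
    binom_multi = binomial_sign_test(max(table.a, table.b), n_multi) if n_multi else None
    binom_single = binomial_sign_test(max(table.c, table.d), n_single) if n_single else None
    return ConcordanceResult(
        table=table, fisher=fisher, chi2=chi2,
        binomial_multi=binom_multi, binomial_single=binom_single,
    )


def stratified_correlations(
    classified_pairs: Sequence[HomologPair], strict: bool = False
) -> dict[str, CorrelationSuite]:
    """Correlation suites for the multi- and single-support strata.

    Inclusive membership (default) goes by the focal gene's total pair
    count k across all relations: pairs of a focal gene with k >= 2 form
    the multi-support stratum (orthologs with multiple homologs plus
    their paralog companions), pairs of a focal gene with k == 1 form the
    single stratum. ``strict=True`` keeps only orthologous pairs in each
    stratum.
    """
    counts: dict[str, int] = {}
    for p in classified_pairs:
        sym = normalize_symbol(p.focal.symbol)
        counts[sym] = counts.get(sym, 0) + 1
    multi, single = [], []
    for p in classified_pairs:
        if strict and p.relation is not Relation.ORTHOLOG:
            continue
        sym = normalize_symbol(p.focal.symbol)
        (multi if counts[sym] >= 2 else single).append(p)
    out: dict[str, CorrelationSuite] = {}
    for name, stratum in (("multi", multi), ("single", single)):
        if len(stratum) < 3:
            raise ValueError(f"stratum {name!r} has fewer than 3 pairs")
        x, y = _as_xy(stratum)
        out[name] = correlation_suite(x, y)
    return out
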