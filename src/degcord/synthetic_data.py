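"""Generators for paired log2 fold changes and qPCR replicate matrices.

``simulate_paired_log2`` draws, per gene, a shared sign and two
magnitudes; with probability ``common_fraction`` the comparison keeps the
focal sign ("common" genes), otherwise its sign is re-drawn uniformly
("variable" genes), so the expected sign-concordant share is
f + (1 - f) / 2. Magnitudes default to log-uniform on [0.25, 7.5].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .qpcr import QPCRSample

__all__ = [
    "PairSimParams",
    "QPCRSimParams",
    "simulate_paired_log2",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class PairSimParams:
    n_genes: int
    common_fraction: float = 0.7
    magnitude_low: float = 0.25
    magnitude_high: float = 7.5
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (0.0 <= self.common_fraction <= 1.0):
            raise ValueError("common_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0 < self.magnitude_low <= self.magnitude_high):
            raise ValueError("magnitude bounds must be positive and ordered")


@dataclass(frozen=True)
class QPCRSimParams:
    n_per_group: int = 8
    mean_low: float = 0.3
    mean_high: float = 2.0
    cv: float = 0.4
    detection_limit: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.mean_low <= 0 or self.mean_high <= 0:
            raise ValueError("group means must be positive")
        if self.cv < 0 or self.detection_limit <= 0:
            raise ValueError("cv must be >= 0 and detection_limit > 0")


def _log_uniform(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    if low == high:
        return np.full(size, low)
    return np.exp(rng.uniform(np.log(low), np.log(high), size))


def simulate_paired_log2(params: PairSimParams):
    """Return (pairs, labels): n x 2 array of log2 values + common/variable.

    Per-gene streams are derived from the single seed so any prefix of the
    output is reproducible independent of ``n_genes``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    signs = rng.choice([-1.0, 1.0], size=n)
    m1 = _log_uniform(rng, params.magnitude_low, params.magnitude_high, n)
    m2 = _log_uniform(rng, params.magnitude_low, params.magnitude_high, n)
    common = rng.random(n) < params.common_fraction
    comp_signs = np.where(common, signs, rng.choice([-1.0, 1.0], size=n))
    x = signs * m1
    y = comp_signs * m2
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, n)
        y = y + rng.normal(0.0, params.noise_sd, n)
    labels = np.where(common, "common", "variable")
    return np.column_stack([x, y]), labels


def simulate_qpcr(params: QPCRSimParams, gene: str = "simgene") -> list[QPCRSample]:
    """Log-normal per-animal expression around each group mean.

    Values at or below ``detection_limit`` are flagged ND. The low-mean
    group mimics the aggressive set, the high-mean group the tame set.
    """
    rng = np.random.default_rng(params.seed)
    samples: list[QPCRSample] = []
    for group, mu, score in (("aggressive", params.mean_low, -3), ("tame", params.mean_high, 3)):
        if params.cv > 0:
            sigma2 = np.log1p(params.cv**2)
            draw = rng.lognormal(np.log(mu) - sigma2 / 2, np.sqrt(sigma2), params.n_per_group)
        else:
            draw = np.full(params.n_per_group, mu)
        for i, v in enumerate(draw, start=1):
            nd = bool(v <= params.detection_limit)
            samples.append(
                QPCRSample(gene=gene, animal_id=i, group=group, behavior_score=score,
                           rel_expr=None if nd else float(v), nd_flag=nd)
            )
    return samples
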