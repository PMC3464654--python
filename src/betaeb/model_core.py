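"""Domain types and marginal densities of the lognormal–normal (LNN) hierarchy.

Log-scale expression values of gene ``t`` are modelled as Gaussian around a
gene-specific mean ``mu_t`` with gene-specific variance ``sigma_t^2``; the gene
means themselves are Gaussian, ``mu_t ~ N(mu0, tau0^2)``.  Integrating out the
gene mean yields an n-dimensional Gaussian marginal with mean ``mu0 * 1`` and
the exchangeable covariance

    Sigma_tn = sigma_t^2 * I_n + tau0^2 * M_n,

where ``M_n`` is the all-ones matrix.  A gene is either equivalently expressed
(EE: one shared mean across both sample groups, marginal ``f0``) or
differentially expressed (DE: independent group means, marginal
``f1 = f0(group 1) * f0(group 2)``); the observed-data likelihood is the
two-component mixture ``p0*f0 + p1*f1``.

Everything here is pure computation on which the EM fit, the β-weight
diagnostics and the PPDE scores are built.  All density arithmetic is done in
log space, and the exchangeable covariance is inverted through its rank-one
closed form (never densely).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ExpressionData",
    "HyperParams",
    "VariancePrior",
    "GeneScale",
    "GeneScaleTable",
    "BetaConfig",
    "exchangeable_cov_ops",
    "log_f0",
    "log_f1",
    "log_mixture",
]


class InvalidScaleError(ValueError):
    """Raised when a variance parameter is non-positive where positivity is required."""


@dataclass(frozen=True)
class HyperParams:
    """Hyper-parameters of the gene-mean prior and the EE/DE mixture.

    Parameters
    ----------
    mu0 : prior mean of the gene means (log-expression units).
    tau0_sq : prior variance of the gene means; ``>= 0``.
    p1 : mixing proportion of DE genes; ``p0 = 1 - p1``.
    """

    mu0: float
    tau0_sq: float
    p1: float

    def __post_init__(self) -> None:
        if self.tau0_sq < 0:
            raise ValueError(f"tau0_sq must be >= 0, got {self.tau0_sq}")
        if not 0.0 <= self.p1 <= 1.0:
            raise ValueError(f"p1 must lie in [0, 1], got {self.p1}")

    @property
    def p0(self) -> float:
        return 1.0 - self.p1


@dataclass(frozen=True)
class VariancePrior:
    """Scale-inverse-χ²(ν*, σ*²) prior for the gene-specific variances."""

    nu_star: float
    sigma_star_sq: float

    def __post_init__(self) -> None:
        if self.nu_star <= 0:
            raise ValueError(f"nu_star must be > 0, got {self.nu_star}")
        if self.sigma_star_sq <= 0:
            raise ValueError(f"sigma_star_sq must be > 0, got {self.sigma_star_sq}")


@dataclass(frozen=True)
class GeneScale:
    """Per-gene robust location/scale summary for the two sample groups."""

    mu_t1: float
    mu_t2: float
    sigma_t1_sq: float
    sigma_t2_sq: float
    sigma_tilde_sq: float
    sigma_hat_sq: float


@dataclass
class GeneScaleTable:
    """Columnar table of :class:`GeneScale` rows plus the fitted variance prior."""

    mu1: np.ndarray
    mu2: np.ndarray
    sigma1_sq: np.ndarray
    sigma2_sq: np.ndarray
    sigma_tilde_sq: np.ndarray
    sigma_hat_sq: np.ndarray
    prior: VariancePrior

    def __len__(self) -> int:
        return self.mu1.shape[0]

    def row(self, t: int) -> GeneScale:
        return GeneScale(
            mu_t1=float(self.mu1[t]),
            mu_t2=float(self.mu2[t]),
            sigma_t1_sq=float(self.sigma1_sq[t]),
            sigma_t2_sq=float(self.sigma2_sq[t]),
            sigma_tilde_sq=float(self.sigma_tilde_sq[t]),
            sigma_hat_sq=float(self.sigma_hat_sq[t]),
        )


@dataclass(frozen=True)
class BetaConfig:
    """Robustness tuning parameters.

    ``beta`` weights the mixture fit (0 recovers the classical EB-LNN EM),
    ``beta0`` is the reference parameter of the predictive score used in
    cross-validated selection of ``beta``, and ``beta_scale`` is the fixed
    β used inside the per-gene robust mean/variance iteration (0.1 by default).
    """

    beta: float = 0.015
    beta0: float = 0.005
    beta_scale: float = 0.1

    def __post_init__(self) -> None:
        for name in ("beta", "beta0", "beta_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ExpressionData:
    """A genes × samples log-expression matrix with a two-group design.

    ``values`` holds log-scale expression (natural log applied at ingestion
    unless ``is_logged``), ``group_labels`` assigns each sample to group 1 or 2.
    """

    values: np.ndarray
    group_labels: np.ndarray
    gene_ids: Sequence[str] | None = None
    sample_ids: Sequence[str] | None = None
    is_logged: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        T, n = self.values.shape
        if T < 2:
            raise ValueError("need at least 2 genes")
        if self.group_labels.shape != (n,):
            raise ValueError("group_labels length must match the number of samples")
        if not set(np.unique(self.group_labels)) <= {1, 2}:
            raise ValueError("group_labels must be in {1, 2}")
        if np.isnan(self.values).any():
            raise ValueError("values contain missing entries after ingestion")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.gene_ids is None:
            self.gene_ids = [f"g{i}" for i in range(T)]
        if self.sample_ids is None:
            self.sample_ids = [f"s{j}" for j in range(n)]

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.group_labels == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.group_labels == 2))

    @property
    def group1(self) -> np.ndarray:
        """T × n1 sub-matrix of group-1 samples."""
        return self.values[:, self.group_labels == 1]

    @property
    def group2(self) -> np.ndarray:
        return self.values[:, self.group_labels == 2]

    def subset_genes(self, idx: np.ndarray) -> "ExpressionData":
        return ExpressionData(
            values=self.values[idx],
            group_labels=self.group_labels.copy(),
            gene_ids=[self.gene_ids[i] for i in np.atleast_1d(np.arange(self.n_genes)[idx])],
            sample_ids=list(self.sample_ids),
            is_logged=self.is_logged,
        )

    def copy(self) -> "ExpressionData":
        return ExpressionData(
            values=self.values.copy(),
            group_labels=self.group_labels.copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            is_logged=self.is_logged,
        )


# ---------------------------------------------------------------------------
# Exchangeable covariance algebra:  Sigma = sigma^2 I + tau^2 M  (M = ones)
#
# Sherman–Morrison with M = 1 1^T gives
#   Sigma^{-1} = (1/sigma^2) [ I − tau^2/(sigma^2 + n tau^2) * M ]
#   |Sigma|    = (sigma^2)^{n-1} (sigma^2 + n tau^2)
# so the quadratic form needs only sum(x) and sum(x^2).
# ---------------------------------------------------------------------------


def exch_log_det(sigma_sq, tau0_sq, n: int):
    """log|σ²I + τ²M| for scalar or array ``sigma_sq``."""
    sigma_sq = np.asarray(sigma_sq, dtype=float)
    if np.any(sigma_sq <= 0):
        raise InvalidScaleError("sigma_t_sq must be positive")
    return (n - 1) * np.log(sigma_sq) + np.log(sigma_sq + n * tau0_sq)


def exch_quad_form(sum_x, sum_x_sq, sigma_sq, tau0_sq, n: int):
    """x^T Σ⁻¹ x from the sufficient statistics sum(x), sum(x²)."""
    return sum_x_sq / sigma_sq - tau0_sq * sum_x**2 / (sigma_sq * (sigma_sq + n * tau0_sq))


def exchangeable_cov_ops(
    sigma_t_sq: float, tau0_sq: float, n: int
) -> tuple[float, Callable[[np.ndarray], float]]:
    """Closed-form determinant and quadratic-form evaluator for σ²I + τ²M.

    Returns ``(log_det, quad)`` where ``quad(x)`` evaluates ``x^T Σ⁻¹ x``
    in O(n) via the rank-one update, never through a dense inverse.
    """
    if sigma_t_sq <= 0:
        raise InvalidScaleError(f"sigma_t_sq must be positive, got {sigma_t_sq}")
    if n < 1:
        raise ValueError("n must be >= 1")
    log_det = float(exch_log_det(sigma_t_sq, tau0_sq, n))

    def quad(x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (n,):
            raise ValueError(f"expected a length-{n} vector, got shape {x.shape}")
        return float(exch_quad_form(x.sum(), (x**2).sum(), sigma_t_sq, tau0_sq, n))

    return log_det, quad


_LOG_2PI = np.log(2.0 * np.pi)


def log_f0_suff(sum_y, sum_y_sq, n: int, theta: HyperParams, sigma_sq):
    """Vectorised EE log-marginal from per-gene sufficient statistics.

    ``sum_y``, ``sum_y_sq`` and ``sigma_sq`` may be arrays over genes.
    """
    sum_x = sum_y - n * theta.mu0
    sum_x_sq = sum_y_sq - 2.0 * theta.mu0 * sum_y + n * theta.mu0**2
    q = exch_quad_form(sum_x, sum_x_sq, sigma_sq, theta.tau0_sq, n)
    return -0.5 * (n * _LOG_2PI + exch_log_det(sigma_sq, theta.tau0_sq, n) + q)


def log_f0(y: np.ndarray, theta: HyperParams, sigma_t_sq: float) -> float:
    """EE log-marginal: N(μ₀·1, σ_t²I + τ₀²M) evaluated at ``y``."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("y must be a 1-D vector")
    if sigma_t_sq <= 0:
        raise InvalidScaleError(f"sigma_t_sq must be positive, got {sigma_t_sq}")
    return float(log_f0_suff(y.sum(), (y**2).sum(), y.shape[0], theta, sigma_t_sq))


def log_f1(y1: np.ndarray, y2: np.ndarray, theta: HyperParams, sigma_t_sq: float) -> float:
    """DE log-marginal: the group means are integrated out independently,
    so the density factorises into the per-group EE marginals."""
    return log_f0(y1, theta, sigma_t_sq) + log_f0(y2, theta, sigma_t_sq)


def log_mixture(y1: np.ndarray, y2: np.ndarray, theta: HyperParams, sigma_t_sq: float) -> float:
    """log(p0·f0(y) + p1·f1(y1,y2)) via log-sum-exp; ``y`` is the concatenation."""
    y = np.concatenate([np.asarray(y1, float), np.asarray(y2, float)])
    lf0 = log_f0(y, theta, sigma_t_sq)
    lf1 = log_f1(y1, y2, theta, sigma_t_sq)
    return float(_log_mix(lf0, lf1, theta.p1))


def _log_mix(lf0, lf1, p1: float):
    """Stable log(p0 e^{lf0} + p1 e^{lf1}) handling the degenerate endpoints."""
    if p1 == 0.0:
        return lf0
    if p1 == 1.0:
        return lf1
    a = np.log1p(-p1) + lf0
    b = np.log(p1) + lf1
    hi = np.maximum(a, b)
    return hi + np.log1p(np.exp(-np.abs(a - b)))


@dataclass
class SuffStats:
    """Cached per-gene sufficient statistics for fast density evaluation."""

    s1_g1: np.ndarray  # sum of group-1 values per gene
    s2_g1: np.ndarray  # sum of squares, group 1
    s1_g2: np.ndarray
    s2_g2: np.ndarray
    n1: int
    n2: int

    @classmethod
    def from_data(cls, data: ExpressionData) -> "SuffStats":
        g1, g2 = data.group1, data.group2
        return cls(
            s1_g1=g1.sum(axis=1),
            s2_g1=(g1**2).sum(axis=1),
            s1_g2=g2.sum(axis=1),
            s2_g2=(g2**2).sum(axis=1),
            n1=data.n1,
            n2=data.n2,
        )

    def log_f0_all(self, theta: HyperParams, sigma_sq: np.ndarray) -> np.ndarray:
        """EE log-marginal of the full n-vector, per gene."""
        return log_f0_suff(
            self.s1_g1 + self.s1_g2,
            self.s2_g1 + self.s2_g2,
            self.n1 + self.n2,
            theta,
            sigma_sq,
        )

    def log_f1_all(self, theta: HyperParams, sigma_sq: np.ndarray) -> np.ndarray:
        """DE log-marginal (product of per-group EE marginals), per gene."""
        return log_f0_suff(self.s1_g1, self.s2_g1, self.n1, theta, sigma_sq) + log_f0_suff(
            self.s1_g2, self.s2_g2, self.n2, theta, sigma_sq
        )
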