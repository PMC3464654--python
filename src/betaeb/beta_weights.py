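"""Gene-level β-weights, their null distribution, and contamination repair.

A gene's β-weight is the negative exponential of its squared Mahalanobis
distance from the fitted marginal,

    w_t = exp(-(beta/2) * MD_t),    MD_t = (y_t - mu0)' Sigma_tn^{-1} (y_t - mu0),

using the EE covariance for the whole profile (k = 0) or the two group-wise
covariances for the DE pattern (k = 1).  Under the model with known variance,
MD_t is χ² distributed (n degrees of freedom; the group-wise forms add), which
gives a closed-form null CDF for the weights; with heterogeneous estimated
variances the null is obtained by parametric bootstrap from the fitted model.
Genes whose weight falls below the null p-quantile ξ_p (default p = 1e-5) are
flagged as contaminated, and within flagged genes individual measurements with
per-measurement ψ_β weight below a threshold (fixed α₀ = 0.2 by default, or
the χ²₁-based quantile α_p) are replaced by the robust group mean.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model_core import (
    ExpressionData,
    GeneScaleTable,
    HyperParams,
    SuffStats,
    exchangeable_cov_ops,
)
from .robust_scale import psi_beta

__all__ = [
    "WeightReport",
    "gene_weight_ee",
    "gene_weight_de",
    "gene_weights_table",
    "weight_null_cdf",
    "weight_null_quantile",
    "weight_null_bootstrap",
    "detect_contaminated_genes",
    "measurement_threshold",
    "detect_and_repair_measurements",
]

logger = logging.getLogger(__name__)

DEFAULT_TAIL_P = 1e-5
DEFAULT_ALPHA0 = 0.2


@dataclass
class WeightReport:
    """Per-gene β-weights with null quantile, gene and measurement flags."""

    w_t: np.ndarray
    md_t: np.ndarray
    xi_p: float
    flagged_genes: np.ndarray  # integer indices
    alpha0: float = DEFAULT_ALPHA0
    alpha_p: float | None = None
    flagged_measurements: list = field(default_factory=list)  # (gene, sample) pairs
    tail_p: float = DEFAULT_TAIL_P
    beta: float = 0.0

    def to_frame(self, gene_ids=None) -> pd.DataFrame:
        T = self.w_t.shape[0]
        flags = np.zeros(T, dtype=bool)
        flags[self.flagged_genes] = True
        return pd.DataFrame(
            {
                "gene_id": gene_ids if gene_ids is not None else np.arange(T),
                "w_t": self.w_t,
                "md_t": self.md_t,
                "flagged": flags,
            }
        )

    def measurements_frame(self, gene_ids=None, sample_ids=None) -> pd.DataFrame:
        rows = [
            {
                "gene_id": gene_ids[t] if gene_ids is not None else t,
                "sample_id": sample_ids[i] if sample_ids is not None else i,
            }
            for t, i in self.flagged_measurements
        ]
        return pd.DataFrame(rows, columns=["gene_id", "sample_id"])


def _md_ee(y: np.ndarray, theta: HyperParams, sigma_t_sq: float) -> float:
    y = np.asarray(y, dtype=float)
    _, quad = exchangeable_cov_ops(sigma_t_sq, theta.tau0_sq, y.shape[0])
    return quad(y - theta.mu0)


def gene_weight_ee(y: np.ndarray, theta: HyperParams, sigma_t_sq: float, beta: float) -> float:
    """EE-pattern β-weight of a full expression profile."""
    if beta == 0.0:
        logger.warning("beta=0 makes every gene weight 1 (degenerate)")
        return 1.0
    return float(np.exp(-0.5 * beta * _md_ee(y, theta, sigma_t_sq)))


def gene_weight_de(
    y1: np.ndarray, y2: np.ndarray, theta: HyperParams, sigma_t_sq: float, beta: float
) -> float:
    """DE-pattern β-weight: group-wise Mahalanobis distances add in the exponent."""
    if beta == 0.0:
        logger.warning("beta=0 makes every gene weight 1 (degenerate)")
        return 1.0
    md = _md_ee(y1, theta, sigma_t_sq) + _md_ee(y2, theta, sigma_t_sq)
    return float(np.exp(-0.5 * beta * md))


def _md_de_all(stats: SuffStats, theta: HyperParams, sigma_sq: np.ndarray) -> np.ndarray:
    """Vectorised DE-pattern squared Mahalanobis distance per gene."""
    from .model_core import exch_quad_form

    out = np.zeros_like(np.asarray(sigma_sq, dtype=float))
    for s1, s2, n in ((stats.s1_g1, stats.s2_g1, stats.n1), (stats.s1_g2, stats.s2_g2, stats.n2)):
        sx = s1 - n * theta.mu0
        sxx = s2 - 2 * theta.mu0 * s1 + n * theta.mu0**2
        out += exch_quad_form(sx, sxx, sigma_sq, theta.tau0_sq, n)
    return out


def gene_weights_table(
    data: ExpressionData, theta: HyperParams, scales: GeneScaleTable, beta: float
) -> tuple[np.ndarray, np.ndarray]:
    """(w_t, MD_t) for every gene using the DE-pattern weight form."""
    stats = SuffStats.from_data(data)
    md = _md_de_all(stats, theta, scales.sigma_hat_sq)
    if beta == 0.0:
        return np.ones_like(md), md
    return np.exp(-0.5 * beta * md), md


def weight_null_cdf(w0, beta: float, df: int):
    """P(w ≤ w0) under the null that MD = -(2/β)·log w is χ²_df.

    Small weights correspond to the χ² upper tail, so the CDF is the
    survival function of χ²_df evaluated at -(2/β)·log w0.
    """
    w0 = np.asarray(w0, dtype=float)
    if np.any((w0 <= 0) | (w0 > 1)):
        raise ValueError("w0 must lie in (0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return sps.chi2.sf(-2.0 / beta * np.log(w0), df)


def weight_null_quantile(p: float, beta: float, df: int) -> float:
    """ξ_p: the null p-quantile of the β-weight (inverse of weight_null_cdf)."""
    return float(np.exp(-0.5 * beta * sps.chi2.isf(p, df)))


def weight_null_bootstrap(
    theta: HyperParams,
    scales: GeneScaleTable,
    beta: float,
    n1: int,
    n2: int,
    n_boot: int = 1_000_000,
    seed: int = 0,
    reestimate_variance: bool = False,
    beta_scale: float = 0.1,
) -> np.ndarray:
    """Parametric-bootstrap null sample of DE-pattern gene weights (sorted).

    Each bootstrap gene draws its variance from the fitted {σ̂_t²}, its two
    group means independently from N(μ₀, τ₀²) (the pattern under which the
    χ² additivity of the weight exponent is exact) and its measurements from
    the Gaussian observation model.  With ``reestimate_variance`` the robust
    variance pipeline is re-run per bootstrap gene so that the null also
    carries variance-estimation noise (slower; off by default).
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    rng = np.random.default_rng(seed)
    sigma = rng.choice(scales.sigma_hat_sq, size=n_boot, replace=True)
    sd = np.sqrt(sigma)
    tau = np.sqrt(theta.tau0_sq)
    weights = np.empty(n_boot)
    chunk = 200_000
    for lo in range(0, n_boot, chunk):
        hi = min(lo + chunk, n_boot)
        m = hi - lo
        mu_g1 = theta.mu0 + tau * rng.standard_normal(m)
        mu_g2 = theta.mu0 + tau * rng.standard_normal(m)
        y1 = mu_g1[:, None] + sd[lo:hi, None] * rng.standard_normal((m, n1))
        y2 = mu_g2[:, None] + sd[lo:hi, None] * rng.standard_normal((m, n2))
        if reestimate_variance:
            from .robust_scale import _robust_stats_matrix, shrink_variance

            _, v1, _ = _robust_stats_matrix(y1, beta_scale, unbiased=True)
            _, v2, _ = _robust_stats_matrix(y2, beta_scale, unbiased=True)
            pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            sig_eval = shrink_variance(pooled, n1, n2, scales.prior)
        else:
            sig_eval = sigma[lo:hi]
        md = np.zeros(m)
        for y, n in ((y1, n1), (y2, n2)):
            x = y - theta.mu0
            sx = x.sum(axis=1)
            sxx = (x**2).sum(axis=1)
            md += sxx / sig_eval - theta.tau0_sq * sx**2 / (
                sig_eval * (sig_eval + n * theta.tau0_sq)
            )
        weights[lo:hi] = np.exp(-0.5 * beta * md)
    weights.sort()
    return weights


def detect_contaminated_genes(
    weights: np.ndarray,
    null,
    p: float = DEFAULT_TAIL_P,
) -> tuple[np.ndarray, float]:
    """Flag genes whose weight falls below the null p-quantile ξ_p.

    ``null`` is either a sorted bootstrap sample of null weights or a tuple
    ``("chi2", beta, df)`` selecting the theoretical CDF.  Returns
    ``(flagged_indices, xi_p)``.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    weights = np.asarray(weights, dtype=float)
    if p == 1.0:
        return np.arange(weights.shape[0]), 1.0 + 0.0  # every weight is <= 1
    if isinstance(null, tuple) and null[0] == "chi2":
        _, beta, df = null
        xi_p = weight_null_quantile(p, beta, df)
    else:
        xi_p = float(np.quantile(np.asarray(null, dtype=float), p))
    flagged = np.flatnonzero(weights < xi_p)
    return flagged, xi_p


def measurement_threshold(beta_scale: float, p: float | None = None, alpha0: float = DEFAULT_ALPHA0) -> float:
    """Measurement-level ψ_β threshold: fixed α₀ or the χ²₁-based quantile α_p."""
    if p is None:
        return alpha0
    return float(np.exp(-0.5 * beta_scale * sps.chi2.isf(p, 1)))


def detect_and_repair_measurements(
    data: ExpressionData,
    flagged_genes: np.ndarray,
    scales: GeneScaleTable,
    beta_scale: float = 0.1,
    alpha0: float = DEFAULT_ALPHA0,
    tail_p: float | None = None,
) -> tuple[ExpressionData, list]:
    """Replace contaminated measurements of flagged genes by the robust group mean.

    Within each flagged gene and group, a measurement is contaminated when its
    ψ_β weight (computed from the robust group mean/variance at ``beta_scale``)
    falls below the threshold — fixed ``alpha0`` (default 0.2) or, when
    ``tail_p`` is given, the χ²₁ quantile α_p.  Only flagged genes are
    modified.  Returns the repaired copy and the (gene, sample) flag list.
    """
    thr = measurement_threshold(beta_scale, tail_p, alpha0)
    repaired = data.copy()
    flags: list[tuple[int, int]] = []
    g1_idx = np.flatnonzero(data.group_labels == 1)
    g2_idx = np.flatnonzero(data.group_labels == 2)
    for t in np.atleast_1d(np.asarray(flagged_genes, dtype=int)):
        for idx, mu, var in (
            (g1_idx, scales.mu1[t], scales.sigma1_sq[t]),
            (g2_idx, scales.mu2[t], scales.sigma2_sq[t]),
        ):
            w = psi_beta(repaired.values[t, idx], mu, var, beta_scale)
            bad = idx[w < thr]
            repaired.values[t, bad] = mu
            flags.extend((int(t), int(i)) for i in bad)
    return repaired, flags
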