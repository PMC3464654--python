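"""Posterior probability of differential expression and the β-PPDE pipeline.

The PPDE of gene t is the posterior weight of the DE pattern,
``p1 f1 / (p0 f0 + p1 f1)``.  The full β-PPDE workflow is: robust per-gene
scales → (optional CV selection of β) → β-likelihood EM fit → gene β-weights
and contamination flags against the null → repair of contaminated
measurements → PPDE recomputed for the repaired genes with the *previous*
parameter estimates (no refit, matching the method's design; a refit flag
exists for sensitivity analysis).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import beta_select, beta_weights, em_fit
from .em_fit import FitResult
from .model_core import BetaConfig, ExpressionData, GeneScaleTable, HyperParams
from .robust_scale import gene_scale_table

__all__ = ["compute_ppde", "PipelineResult", "beta_ppde_pipeline"]


def compute_ppde(
    data: ExpressionData, theta: HyperParams, scales: GeneScaleTable
) -> np.ndarray:
    """Per-gene posterior probability of differential expression in [0, 1]."""
    return em_fit.posterior_patterns(data, theta, scales)[:, 1]


@dataclass
class PipelineResult:
    fit: FitResult
    weights: beta_weights.WeightReport
    ppde: np.ndarray
    ppde_after_repair: np.ndarray
    repaired_data: ExpressionData
    scales: GeneScaleTable
    beta: float
    cv_table: pd.DataFrame | None = None

    def to_frame(self, gene_ids=None) -> pd.DataFrame:
        T = self.ppde.shape[0]
        flags = np.zeros(T, dtype=bool)
        flags[self.weights.flagged_genes] = True
        n_rep = np.zeros(T, dtype=int)
        for t, _ in self.weights.flagged_measurements:
            n_rep[t] += 1
        return pd.DataFrame(
            {
                "gene_id": gene_ids if gene_ids is not None else np.arange(T),
                "ppde": self.ppde,
                "ppde_after_repair": self.ppde_after_repair,
                "w_t": self.weights.w_t,
                "flagged": flags,
                "n_repaired_measurements": n_rep,
            }
        )


def beta_ppde_pipeline(
    data: ExpressionData,
    cfg: BetaConfig | None = None,
    select_beta: bool = False,
    seed: int = 0,
    tail_p: float = beta_weights.DEFAULT_TAIL_P,
    alpha0: float = beta_weights.DEFAULT_ALPHA0,
    n_boot: int = 1_000_000,
    refit_after_repair: bool = False,
    grid=beta_select.DEFAULT_GRID,
    common_variance: bool = False,
    fit_kwargs: dict | None = None,
) -> PipelineResult:
    """Full robust differential-expression workflow, seeded end-to-end.

    ``common_variance`` replaces the per-gene shrunken variances by the mean
    pooled variance shared across genes — the classical LNN variance model,
    used for the EB-LNN comparator.
    """
    cfg = cfg or BetaConfig()
    fit_kwargs = fit_kwargs or {}
    scales = gene_scale_table(data, cfg)
    if common_variance:
        scales.sigma_hat_sq = np.full_like(
            scales.sigma_hat_sq, float(np.mean(scales.sigma_tilde_sq))
        )
    cv_table = None
    beta = cfg.beta
    if select_beta:
        beta, cv_table = beta_select.select_beta(
            data, grid=grid, beta0=cfg.beta0, seed=seed, beta_scale=cfg.beta_scale,
            fit_kwargs=fit_kwargs,
        )
    res = em_fit.fit(data, beta=beta, scales=scales, **fit_kwargs)
    ppde = res.posterior[:, 1].copy()

    if beta > 0:
        w, md = beta_weights.gene_weights_table(data, res.theta, scales, beta)
        null = beta_weights.weight_null_bootstrap(
            res.theta, scales, beta, data.n1, data.n2, n_boot=n_boot, seed=seed
        )
        flagged, xi_p = beta_weights.detect_contaminated_genes(w, null, p=tail_p)
        repaired, meas_flags = beta_weights.detect_and_repair_measurements(
            data, flagged, scales, beta_scale=cfg.beta_scale, alpha0=alpha0
        )
        report = beta_weights.WeightReport(
            w_t=w,
            md_t=md,
            xi_p=xi_p,
            flagged_genes=flagged,
            alpha0=alpha0,
            flagged_measurements=meas_flags,
            tail_p=tail_p,
            beta=beta,
        )
        if refit_after_repair:
            res_rep = em_fit.fit(repaired, beta=beta, scales=scales, **fit_kwargs)
            ppde_after = res_rep.posterior[:, 1]
        else:
            # previous parameter estimates, no refit
            ppde_after = compute_ppde(repaired, res.theta, scales)
    else:
        w, md = beta_weights.gene_weights_table(data, res.theta, scales, beta)
        report = beta_weights.WeightReport(
            w_t=w, md_t=md, xi_p=0.0, flagged_genes=np.array([], dtype=int), beta=beta
        )
        repaired = data
        ppde_after = ppde.copy()

    return PipelineResult(
        fit=res,
        weights=report,
        ppde=ppde,
        ppde_after_repair=ppde_after,
        repaired_data=repaired,
        scales=scales,
        beta=beta,
        cv_table=cv_table,
    )
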