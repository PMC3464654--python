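"""ROC- and FDR-based performance metrics and the scenario benchmark runner.

AUC ranks genes by a DE score against the truth labels; pAUC is the
*unnormalized* area of the ROC curve restricted to FPR ≤ 0.2 (maximum 0.2).
DE calling at a target FDR uses the direct-posterior-probability rule: sort by
1 − PPDE ascending and call the largest prefix whose running mean of
(1 − PPDE) stays at or below the level.
"""
from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .model_core import BetaConfig
from .ppde import beta_ppde_pipeline
from .simulator import preset_config, simulate_lnn

__all__ = ["roc_auc", "partial_auc", "fdr_metrics", "scenario_benchmark"]

logger = logging.getLogger(__name__)


def _check_truth(truth: np.ndarray) -> np.ndarray:
    truth = np.asarray(truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("truth must contain both DE and non-DE genes")
    return truth


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Trapezoidal AUC, higher scores meaning more likely DE; ties averaged."""
    truth = _check_truth(truth)
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def partial_auc(scores: np.ndarray, truth: np.ndarray, fpr_max: float = 0.2) -> float:
    """Unnormalized ROC area over FPR ∈ [0, fpr_max], interpolated at the cut."""
    truth = _check_truth(truth)
    fpr, tpr, _ = roc_curve(truth, np.asarray(scores, dtype=float))
    if fpr_max >= 1.0:
        return float(np.trapezoid(tpr, fpr))
    tpr_cut = np.interp(fpr_max, fpr, tpr)
    keep = fpr <= fpr_max
    x = np.r_[fpr[keep], fpr_max]
    y = np.r_[tpr[keep], tpr_cut]
    return float(np.trapezoid(y, x))


def fdr_metrics(ppde: np.ndarray, truth: np.ndarray, fdr_level: float = 0.01) -> dict:
    """Direct-posterior FDR calling and the resulting error rates.

    Returns misclassification rate (MR), false-positive rate (FPR), false
    negative rate (FNR) and the number of genes called.
    """
    ppde = np.asarray(ppde, dtype=float)
    truth = np.asarray(truth).astype(bool)
    order = np.argsort(1.0 - ppde, kind="stable")
    running = np.cumsum(1.0 - ppde[order]) / np.arange(1, ppde.shape[0] + 1)
    ok = np.flatnonzero(running <= fdr_level)
    n_called = int(ok[-1] + 1) if ok.size else 0
    called = np.zeros(ppde.shape[0], dtype=bool)
    called[order[:n_called]] = True
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())
    return {
        "MR": (fp + fn) / truth.shape[0],
        "FPR": fp / n_neg if n_neg else 0.0,
        "FNR": fn / n_pos if n_pos else 0.0,
        "n_called": n_called,
    }


def _run_method(sim, method: str, beta: float, seed: int, n_boot: int, fit_kwargs):
    if method == "eb_lnn":
        # classical LNN comparator: beta = 0, classical moments, and a single
        # observation variance shared across genes (gene-specific variance is
        # what the robust extension adds on top)
        cfg = BetaConfig(beta=0.0, beta_scale=0.0)
        out = beta_ppde_pipeline(
            sim.data, cfg, seed=seed, common_variance=True, fit_kwargs=fit_kwargs
        )
    elif method == "beta_eb":
        cfg = BetaConfig(beta=beta, beta_scale=0.1)
        out = beta_ppde_pipeline(sim.data, cfg, seed=seed, n_boot=n_boot, fit_kwargs=fit_kwargs)
    else:
        raise ValueError(f"unknown method {method!r}")
    return out


def scenario_benchmark(
    presets,
    n_datasets: int = 50,
    methods=("beta_eb", "eb_lnn"),
    seed: int = 0,
    beta: float = 0.015,
    fdr_level: float = 0.01,
    n_boot: int = 200_000,
    fit_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Mean ± SE of p̂₁, AUC, pAUC and FDR-controlled error rates per scenario.

    Runs the full pipeline on ``n_datasets`` independent replicates of each
    named preset for each method; failures are logged and excluded with a
    count.  Emits a long-format table (scenario, method, metric, mean, se,
    n_datasets).
    """
    rows = []
    for preset in presets:
        per_method: dict[str, dict[str, list]] = {
            m: {k: [] for k in ("p1", "AUC", "pAUC", "MR", "FPR", "FNR")} for m in methods
        }
        failures = {m: 0 for m in methods}
        for rep in range(n_datasets):
            rep_seed = seed + 1000 * rep
            sim = simulate_lnn(preset_config(preset, seed=rep_seed))
            for method in methods:
                try:
                    out = _run_method(sim, method, beta, rep_seed, n_boot, fit_kwargs)
                except Exception:
                    logger.exception("%s failed on %s rep %d", method, preset, rep)
                    failures[method] += 1
                    continue
                acc = per_method[method]
                acc["p1"].append(out.fit.theta.p1)
                acc["AUC"].append(roc_auc(out.ppde_after_repair, sim.is_de))
                acc["pAUC"].append(partial_auc(out.ppde_after_repair, sim.is_de))
                fm = fdr_metrics(out.ppde_after_repair, sim.is_de, fdr_level)
                for k in ("MR", "FPR", "FNR"):
                    acc[k].append(fm[k])
        for method in methods:
            if failures[method]:
                logger.warning("%s: %d/%d replicates failed on %s",
                               method, failures[method], n_datasets, preset)
            for metric, vals in per_method[method].items():
                vals = np.asarray(vals, dtype=float)
                se = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
                rows.append(
                    {
                        "scenario": preset,
                        "method": method,
                        "metric": metric,
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "se": se,
                        "n_datasets": int(vals.size),
                    }
                )
    return pd.DataFrame(rows)
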