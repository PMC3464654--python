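"""Independent reference implementations used only to check betaeb.

Everything here deliberately avoids the package's closed forms: dense
covariance matrices, brute-force quadrature, and a from-scratch classical
EM coded against scipy primitives.
"""
from __future__ import annotations

import numpy as np
from scipy import integrate, optimize
from scipy.stats import multivariate_normal, norm


def dense_cov(sigma_sq: float, tau_sq: float, n: int) -> np.ndarray:
    return sigma_sq * np.eye(n) + tau_sq * np.ones((n, n))


def dense_log_det(sigma_sq, tau_sq, n) -> float:
    return float(np.linalg.slogdet(dense_cov(sigma_sq, tau_sq, n))[1])


def dense_quad_form(x, sigma_sq, tau_sq) -> float:
    S = dense_cov(sigma_sq, tau_sq, len(x))
    return float(x @ np.linalg.solve(S, x))


def dense_log_f0(y, mu0, tau_sq, sigma_sq) -> float:
    n = len(y)
    return float(
        multivariate_normal.logpdf(y, mean=np.full(n, mu0), cov=dense_cov(sigma_sq, tau_sq, n))
    )


def quadrature_log_f0(y, mu0, tau_sq, sigma_sq) -> float:
    """Marginal density by numerically integrating the gene mean out."""
    y = np.asarray(y, dtype=float)

    def integrand(mu):
        return np.prod(norm.pdf(y, loc=mu, scale=np.sqrt(sigma_sq))) * norm.pdf(
            mu, loc=mu0, scale=np.sqrt(tau_sq)
        )

    lo = mu0 - 12 * np.sqrt(tau_sq)
    hi = mu0 + 12 * np.sqrt(tau_sq)
    val, _ = integrate.quad(integrand, lo, hi, limit=400)
    return float(np.log(val))


def gaussian_power_integral_quadrature(sigma_tot_sq: float, power: float) -> float:
    """∫ N(y; 0, σ²)^power dy by quadrature (1-D)."""
    s = np.sqrt(sigma_tot_sq)
    val, _ = integrate.quad(lambda y: norm.pdf(y, scale=s) ** power, -40 * s, 40 * s, limit=400)
    return float(val)


def classical_em(
    values: np.ndarray,
    n1: int,
    sigma_hat_sq: np.ndarray,
    mu0: float,
    tau0_sq: float,
    p1: float,
    tol: float = 1e-9,
    max_iter: int = 2000,
):
    """Classical EB-LNN EM with dense densities, coded independently.

    Gene-specific variances are plugged in; the M-step maximises the standard
    Q-function by Nelder–Mead on (mu0, log tau0_sq).  Returns (mu0, tau0_sq, p1).
    """
    T, n = values.shape
    y1 = values[:, :n1]
    y2 = values[:, n1:]

    def logf(th_mu, th_tau):
        lf0 = np.empty(T)
        lf1 = np.empty(T)
        for t in range(T):
            lf0[t] = dense_log_f0(values[t], th_mu, th_tau, sigma_hat_sq[t])
            lf1[t] = dense_log_f0(y1[t], th_mu, th_tau, sigma_hat_sq[t]) + dense_log_f0(
                y2[t], th_mu, th_tau, sigma_hat_sq[t]
            )
        return lf0, lf1

    for _ in range(max_iter):
        lf0, lf1 = logf(mu0, tau0_sq)
        a0 = np.log(1 - p1) + lf0
        a1 = np.log(p1) + lf1
        m = np.maximum(a0, a1)
        denom = m + np.log(np.exp(a0 - m) + np.exp(a1 - m))
        pi1 = np.exp(a1 - denom)
        p1_new = float(pi1.mean())

        def neg_q(x):
            l0, l1 = logf(x[0], np.exp(x[1]))
            return -float(np.mean((1 - pi1) * l0 + pi1 * l1))

        res = optimize.minimize(
            neg_q,
            np.array([mu0, np.log(tau0_sq)]),
            method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-11},
        )
        mu0_new, tau_new = float(res.x[0]), float(np.exp(res.x[1]))
        delta = max(abs(mu0_new - mu0), abs(tau_new - tau0_sq), abs(p1_new - p1))
        mu0, tau0_sq, p1 = mu0_new, tau_new, p1_new
        if delta < tol:
            break
    return mu0, tau0_sq, p1


def pairwise_auc(scores, truth) -> float:
    """AUC by enumerating all positive-negative pairs (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth).astype(bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins / (len(pos) * len(neg)))
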