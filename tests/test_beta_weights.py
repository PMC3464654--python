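"""β-weight functions, their null distribution and contamination repair."""
import numpy as np
import pytest
from scipy import stats as sps

from betaeb import (
    BetaConfig,
    HyperParams,
    detect_and_repair_measurements,
    detect_contaminated_genes,
    gene_scale_table,
    gene_weight_de,
    gene_weight_ee,
    gene_weights_table,
    simulate_lnn,
    weight_null_bootstrap,
    weight_null_cdf,
    weight_null_quantile,
)
from betaeb.simulator import SimConfig

from oracles import dense_quad_form


def _null_de_weights(theta, sigma_sq, n1, n2, beta, size, seed):
    """Simulate DE-pattern genes and their weights directly (test-side MC)."""
    rng = np.random.default_rng(seed)
    tau = np.sqrt(theta.tau0_sq)
    w = np.empty(size)
    for i in range(size):
        mu1 = theta.mu0 + tau * rng.standard_normal()
        mu2 = theta.mu0 + tau * rng.standard_normal()
        y1 = mu1 + np.sqrt(sigma_sq) * rng.standard_normal(n1)
        y2 = mu2 + np.sqrt(sigma_sq) * rng.standard_normal(n2)
        w[i] = gene_weight_de(y1, y2, theta, sigma_sq, beta)
    return w


class TestGeneWeights:
    def test_weight_is_one_at_grand_mean(self, theta):
        y = np.full(6, theta.mu0)
        assert gene_weight_ee(y, theta, 0.2, 0.02) == 1.0
        assert gene_weight_de(y[:3], y[3:], theta, 0.2, 0.02) == 1.0

    def test_matches_dense_mahalanobis(self, rng, theta):
        y = rng.standard_normal(5) + 1.0
        md = dense_quad_form(y - theta.mu0, 0.3, theta.tau0_sq)
        assert gene_weight_ee(y, theta, 0.3, 0.05) == pytest.approx(
            np.exp(-0.025 * md), rel=1e-10
        )

    def test_monotone_in_single_coordinate(self, theta):
        base = np.full(4, theta.mu0)
        prev = 1.0
        for shift in (0.5, 1.0, 2.0, 5.0):
            y = base.copy()
            y[0] += shift
            w = gene_weight_ee(y, theta, 0.2, 0.05)
            assert w < prev
            prev = w

    def test_de_weight_is_product_of_group_ee_weights(self, rng, theta):
        y1, y2 = rng.standard_normal(4), rng.standard_normal(3)
        w = gene_weight_de(y1, y2, theta, 0.4, 0.03)
        assert w == pytest.approx(
            gene_weight_ee(y1, theta, 0.4, 0.03) * gene_weight_ee(y2, theta, 0.4, 0.03),
            rel=1e-12,
        )

    def test_null_exponent_is_chi_square(self, theta):
        """-(2/beta) log w over DE-pattern null genes is chi2 with n1+n2 df."""
        beta = 0.02
        w = _null_de_weights(theta, 0.1, 6, 6, beta, size=5000, seed=0)
        q = -2.0 / beta * np.log(w)
        _, p = sps.kstest(q, "chi2", args=(12,))
        assert p > 0.01

    def test_vectorised_table_matches_scalar(self, small_clean_sim, small_clean_scales, theta):
        w, md = gene_weights_table(small_clean_sim.data, theta, small_clean_scales, 0.02)
        t = 17
        y1 = small_clean_sim.data.group1[t]
        y2 = small_clean_sim.data.group2[t]
        assert w[t] == pytest.approx(
            gene_weight_de(y1, y2, theta, small_clean_scales.sigma_hat_sq[t], 0.02), rel=1e-10
        )
        np.testing.assert_allclose(w, np.exp(-0.01 * md), rtol=1e-12)
        assert np.all((w > 0) & (w <= 1))


class TestWeightNullCdf:
    def test_endpoints(self):
        assert weight_null_cdf(1.0, 0.02, 60) == pytest.approx(1.0)
        assert weight_null_cdf(1e-300, 0.02, 60) == pytest.approx(0.0, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            weight_null_cdf(0.0, 0.02, 60)

    def test_matches_empirical_cdf_of_null_weights(self, theta):
        beta, n1, n2 = 0.02, 30, 30
        w = _null_de_weights(theta, 0.1, n1, n2, beta, size=4000, seed=1)
        grid = np.quantile(w, np.linspace(0.02, 0.98, 25))
        theo = weight_null_cdf(grid, beta, n1 + n2)
        emp = np.searchsorted(np.sort(w), grid, side="right") / w.size
        assert np.max(np.abs(theo - emp)) < 0.02

    def test_quantile_inverts_cdf(self):
        xi = weight_null_quantile(1e-3, 0.015, 60)
        assert weight_null_cdf(xi, 0.015, 60) == pytest.approx(1e-3, rel=1e-9)


class TestWeightNullBootstrap:
    def test_determinism(self, theta, small_clean_scales):
        a = weight_null_bootstrap(theta, small_clean_scales, 0.02, 10, 10, n_boot=2000, seed=3)
        b = weight_null_bootstrap(theta, small_clean_scales, 0.02, 10, 10, n_boot=2000, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_quantile_ordering(self, theta, small_clean_scales):
        w = weight_null_bootstrap(theta, small_clean_scales, 0.02, 10, 10, n_boot=5000, seed=4)
        assert 0 < np.quantile(w, 1e-3) <= np.quantile(w, 0.5) <= 1

    def test_matches_theoretical_cdf_with_known_variance(self, theta, small_clean_scales):
        scales = small_clean_scales
        common = scales.sigma_hat_sq.mean()
        fixed = type(scales)(
            mu1=scales.mu1, mu2=scales.mu2, sigma1_sq=scales.sigma1_sq,
            sigma2_sq=scales.sigma2_sq, sigma_tilde_sq=scales.sigma_tilde_sq,
            sigma_hat_sq=np.full_like(scales.sigma_hat_sq, common), prior=scales.prior,
        )
        w = weight_null_bootstrap(theta, fixed, 0.02, 10, 10, n_boot=10_000, seed=5)
        probs = weight_null_cdf(w, 0.02, 20)
        # PIT: the theoretical CDF of the bootstrap sample should be uniform
        _, p = sps.kstest(probs, "uniform")
        assert p > 0.01

    def test_heterogeneous_variance_null_still_chi2(self, theta, small_clean_scales):
        """Resampled variances enter both simulation and weight, so the
        exponent stays chi-square (the documented literal bootstrap)."""
        w = weight_null_bootstrap(theta, small_clean_scales, 0.02, 10, 10,
                                  n_boot=10_000, seed=6)
        q = -2.0 / 0.02 * np.log(np.clip(w, 1e-300, 1))
        _, p = sps.kstest(q, "chi2", args=(20,))
        assert p > 0.01


class TestDetection:
    def test_p_equal_one_flags_everything(self):
        flagged, _ = detect_contaminated_genes(np.array([0.5, 0.9, 1.0]), ("chi2", 0.02, 10), p=1.0)
        assert flagged.size == 3

    def test_false_flag_rate_on_clean_data(self):
        """Nominal-tail behaviour: fraction below xi_p within binomial error."""
        theta = HyperParams(2.0, 3.0, 0.05)
        beta, n1, n2 = 0.02, 15, 15
        w = _null_de_weights(theta, 0.1, n1, n2, beta, size=8000, seed=7)
        for p in (0.01, 0.001):
            flagged, _ = detect_contaminated_genes(w, ("chi2", beta, n1 + n2), p=p)
            se = np.sqrt(p * (1 - p) / w.size)
            assert abs(flagged.size / w.size - p) < 4 * se + 1e-4

    def test_contaminated_genes_are_flagged(self):
        cfg = SimConfig(T=800, n1=30, n2=30, seed=13, contam_gene_frac=0.10,
                        outlier_multiplier=10.0, outliers_per_gene=1)
        sim = simulate_lnn(cfg)
        scales = gene_scale_table(sim.data, BetaConfig())
        theta = HyperParams(2.0, 3.0, 0.05)
        beta = 0.015
        w, _ = gene_weights_table(sim.data, theta, scales, beta)
        null = weight_null_bootstrap(theta, scales, beta, 30, 30, n_boot=200_000, seed=0)
        flagged, _ = detect_contaminated_genes(w, null, p=1e-5)
        contam = np.flatnonzero(sim.contam_mask.any(axis=1))
        frac_found = np.isin(contam, flagged).mean()
        assert frac_found >= 0.5


class TestRepair:
    def test_threshold_algebra(self):
        """alpha0=0.2 at beta_scale=0.1 corresponds to a ~5.67 sigma residual."""
        thr = np.sqrt(-2.0 / 0.1 * np.log(0.2))
        assert thr == pytest.approx(5.67, abs=0.01)
        from betaeb.robust_scale import psi_beta

        assert psi_beta(thr * 1.001, 0.0, 1.0, 0.1) < 0.2 < psi_beta(thr * 0.999, 0.0, 1.0, 0.1)

    def test_exact_outlier_replaced_and_mean_restored(self):
        cfg = SimConfig(T=200, n1=30, n2=30, seed=23, contam_gene_frac=0.10,
                        outlier_multiplier=10.0, outliers_per_gene=1)
        sim = simulate_lnn(cfg)
        scales = gene_scale_table(sim.data, BetaConfig())
        contam_genes = np.flatnonzero(sim.contam_mask.any(axis=1))
        # pick a gene whose outlier really is extreme relative to its mean
        t = next(t for t in contam_genes
                 if abs(sim.data.values[t][sim.contam_mask[t]][0]
                        - np.median(sim.data.values[t])) > 3)
        repaired, flags = detect_and_repair_measurements(sim.data, np.array([t]), scales)
        i = int(np.flatnonzero(sim.contam_mask[t])[0])
        assert (t, i) in flags
        assert repaired.values[t, i] != sim.data.values[t, i]
        clean_vals = sim.data.values[t, ~sim.contam_mask[t]]
        grp = sim.data.group_labels == sim.data.group_labels[i]
        grp_clean = sim.data.values[t, grp & ~sim.contam_mask[t]]
        se = grp_clean.std(ddof=1) / np.sqrt(grp_clean.size)
        assert abs(repaired.values[t, grp].mean() - grp_clean.mean()) < 2 * se

    def test_unflagged_genes_untouched(self, small_clean_sim, small_clean_scales):
        repaired, flags = detect_and_repair_measurements(
            small_clean_sim.data, np.array([3]), small_clean_scales
        )
        others = np.ones(small_clean_sim.data.n_genes, dtype=bool)
        others[3] = False
        np.testing.assert_array_equal(
            repaired.values[others], small_clean_sim.data.values[others]
        )
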