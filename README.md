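# betaeb — robust β-empirical-Bayes differential expression

`betaeb` identifies differentially expressed (DE) transcripts between two
sample groups from a genes × samples expression matrix, for researchers
analysing microarray or other log-intensity expression data in which a
fraction of genes carry outlying measurements (hybridisation artefacts,
irregular expression in a few samples).  Standard empirical-Bayes fits are
driven off course by such genes; `betaeb` downweights them automatically,
tells you *which* genes and measurements were contaminated, repairs them, and
rescues genes that classical fits misclassify.

## The model and the estimator

Log-expression of gene *t* follows the lognormal–normal (LNN) hierarchy

    y_ti | μ_t ~ N(μ_t, σ_t²),     μ_t ~ N(μ₀, τ₀²).

Integrating out μ_t gives a Gaussian marginal with exchangeable covariance
Σ_tn = σ_t² I + τ₀² M (M the all-ones matrix).  An equivalently expressed
(EE) gene shares one μ_t across both groups (marginal f₀); a DE gene draws
independent group means (marginal f₁ = f₀⁽¹⁾·f₀⁽²⁾).  The data density is the
mixture p₀f₀ + p₁f₁ and the posterior probability of differential expression
is PPDE_t = p₁f₁ / (p₀f₀ + p₁f₁).

Instead of the log-likelihood, the hyper-parameters (μ₀, τ₀², p₁) maximise
the **β-likelihood**

    L_β(θ) = (1/Tβ) Σ_t f^β(y_t | θ) − λ_β(θ),

a density-power-weighted quasi-likelihood: each gene enters the estimating
equations with weight f^β(y_t), so genes with unexpected profiles (low
likelihood) barely influence the fit.  β = 0 recovers the classical EB-LNN
EM exactly; small β > 0 buys robustness at a small efficiency cost.  β is
chosen by 5-fold cross-validated predictive β₀-likelihood over a grid.

Contamination diagnosis uses the **β-weight**
w_t = exp(−(β/2)·MD_t), where MD_t is the squared Mahalanobis distance of the
profile from the fitted marginal.  Under the model, MD_t ~ χ² (n degrees of
freedom), giving a closed-form null distribution for w_t (parametric
bootstrap when gene variances are estimated); genes with w_t below the null
10⁻⁵ quantile ξ_p are flagged, their outlying measurements (per-measurement
weight ψ_β below α₀ = 0.2) are replaced by the robust group mean, and the
PPDE is recomputed — the **β-PPDE**.

Gene variances σ_t² are estimated separately and robustly (ψ_β-weighted
iteration at β = 0.1), then shrunk toward a scale-inverse-χ²(ν*, σ*²) prior
fitted by the method of moments:
σ̂_t² = (ν*σ*² + (n₁+n₂−2)σ̃_t²)/(n₁+n₂+ν*−2).

## Worked example

Simulate a benchmark dataset (1000 genes, 30 + 30 samples, 20% of genes
contaminated with extreme 10× outliers) and run the robust fit:

```sh
betaeb simulate --preset extreme20_large --seed 1 --out-dir sim
betaeb fit --expression sim/expression.tsv --labels sim/labels.tsv \
           --is-logged --beta 0.015 --seed 1 --out-dir fit
```

which prints

```
mu0=2.0957 tau0_sq=3.1882 p1=0.0294 beta=0.015 flagged=187
```

— the fitted prior mean and variance of the gene means (generator truth 2.0
and 3.0), the estimated DE proportion, and 187 genes flagged as contaminated
(200 genes were contaminated by construction).  `fit/ppde.tsv` holds the
per-gene results:

```
gene_id  ppde      ppde_after_repair  w_t       flagged  n_repaired_measurements
g0       0.000946  0.000946           0.603     False    0
g1       0.000413  0.000506           1.76e-09  True     2
```

Gene `g1` carried two outlying measurements (β-weight ≈ 0): they were
replaced by its robust group means and its PPDE recomputed.  A clean gene
(`g0`) is untouched.  Library use mirrors this:
`betaeb.beta_ppde_pipeline(data, BetaConfig(beta=0.015))`.

Other subcommands: `select-beta` (cross-validated choice of β), `weights`
(diagnosis only), `benchmark` (β-EB vs classical EB-LNN over scenario
presets), `scan` (per-marker two-group eQTL-style loop).

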