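# Methods

## Model

Each feature (isoform, gene, or protein) is analyzed independently with a
one-way ANOVA on subtype labels under quasi-Poisson moment assumptions: with
`g(i)` the subtype of sample `i`,

```
E[y_i] = mu_g(i) = exp(beta_g(i)),      Var[y_i] = phi * mu_g(i).
```

Only the first two moments are assumed — no likelihood.  The log link keeps
group means positive and makes contrasts interpretable as log fold changes.
`phi >= 1` captures the strong overdispersion of FPKM-scale data.

## Robust fitting

FPKM matrices contain many exact zeros and occasional extreme outliers, which
is why a plain quasi-Poisson fit (or a classical robust linear regression) is
unusable here.  The estimator solves, per group,

```
sum_{i in g} psi_c(u_i) = 0,     u_i = (y_i - mu_g) / sqrt(phi * mu_g),
```

with the Huber function `psi_c(u) = clip(u, -c, c)`, `c = 1.345` (95% normal
efficiency; configurable).  Implementation notes, all of which matter in
practice:

- **Newton steps, not plain IWLS.**  The update uses the full derivative of
  the score, `d psi/d beta = -psi'(u) (sqrt(mu/phi) + u/2)`; the `u/2` term
  comes from the mean-dependent scale.  Plain IWLS working weights converge
  only linearly (rate ~0.7 under the weight/dispersion coupling) and miss the
  50-iteration budget for a few percent of features; Newton brings >99% of
  features of the default synthetic scenario to `tol = 1e-8` within
  `max_iter = 50`.  A trust region of ±2 on the log scale and a fallback to
  the IWLS denominator guard early iterations with heavy clipping.
- **Dispersion.**  `phi` solves the Huber "Proposal 2"-type equation
  `phi = sum_i w_i^2 r_i^2 / (kappa (n - G))`, where `r` are Pearson
  residuals, `w = psi_c(u)/u` and `kappa = E[psi_c(Z)^2]` under a standard
  normal.  The equation is monotone in `phi` and is solved exactly each
  iteration (sorting and suffix sums); naive fixed-point iteration can drift
  to an outlier-inflated root.  For standard errors and robustness weights,
  `phi` is floored at 1: under-dispersion is not credible on the FPKM scale,
  and an unfloored tiny `phi` in degenerate zero-heavy features clips every
  residual and leaves the score without a root.  The raw estimate is reported
  unfloored.
- **Initialization** at group medians (group means when robustness is off, in
  which case the fit reproduces the closed-form saturated solution
  `mu_g = mean(y_g)` to 1e-8).  A contaminated mean start can inflate the
  initial residual scale enough to hand the dispersion iteration the wrong
  root.
- **Zeros.**  Groups that are entirely zero get a floor mean equal to the
  pseudocount (default 0.01 FPKM) and are flagged; the log link cannot
  produce exactly zero means.
- **Covariance.**  Sandwich of the estimating equation with its full
  empirical derivative:
  `Var(beta_g) = sum psi(u)^2 / (sum psi'(u)(sqrt(mu/phi) + u/2))^2`.
  The design decouples per group, so the covariance is exactly diagonal.
  Omitting the `u/2` scale term (the naive IWLS bread) understates the
  variance of strongly skewed low-expression features by up to 4x and makes
  one-vs-rest p-values an order of magnitude anti-conservative at the tails
  that matter after FDR adjustment.  A model-based variance
  `phi / sum w_i mu_i` is available (`cov_type="model"`) for testing.
- **Non-convergence** is flagged per feature, never raised; downstream
  screens exclude and log non-converged features.

## Two-statistic decision procedure

Testing one subtype against the pooled rest is not enough: a significant
one-vs-rest difference is also produced by features that differ among the
*other* subtypes.  Per feature and target subtype:

- `T1 = (beta_t - mean(beta_others)) / se` (Wald, normal reference,
  two-sided).  The unweighted mean of the other coefficients keeps large
  subtypes from dominating the reference; a pooled (size-weighted) reference
  is available by option.
- `T2` = Wald chi-squared for joint equality of the remaining `G-1`
  coefficients (df `G-2`) using the robust variances; with a diagonal
  covariance this is the precision-weighted dispersion around the weighted
  mean.

P-values are BH-adjusted **across features, separately within each target
subtype, separately for T1 and T2** (the per-subtype family matches the
per-subtype discovery lists the procedure produces; a global family is a
config switch).  A feature is declared subtype-specific via either

- primary path: `FDR1 < 0.01` and `FDR2 > 0.10` and `T1 > 0`;
- rescue path: `FDR1 < 0.01`, `FDR2 > 0.01`, and median fold change > 5
  (medians with a 0.01 pseudocount; tolerates mild rest heterogeneity when
  the effect is large).

Only over-expression counts (`T1 > 0`).  Ranked lists sort by `FDR1`
ascending, then `|T1|` descending, then feature id — a single reproducible
order.

**Pairs.**  For each of the `G(G-1)/2` subtype pairs, `T1` contrasts the mean
of the pair's coefficients against the mean of the rest, and `T2` tests
homogeneity of the remaining `G-2` subtypes (with 3 subtypes the single
remaining group is vacuously homogeneous: df 0, p 1).  A within-pair Wald
equality gate (p >= 0.05, on by default) enforces "similar expression in the
pair" and keeps strong single-subtype markers from leaking into pair calls;
disabling it mimics the minimal reading of the rule.  Decision:
`FDR1 < 0.01`, `FDR2 > 0.1`, `T1 > 0`, within-pair gate.

## Classification

- Per-marker one-vs-rest AUC is computed from expression ranks
  (Mann–Whitney with midrank ties) — identical to the ROC area of a
  one-feature logistic classifier by monotone invariance and fast enough for
  ~50k features x 5 subtypes.  Validation AUCs use held-out samples only.
- Gene-level AUCs use gene-level matrices (gene FPKM = sum of isoform FPKM);
  the per-isoform delta (isoform AUC − gene AUC) summarizes when isoform
  resolution beats the gene.  Single-isoform genes give delta exactly 0.
- Panels: L1-penalized logistic regression on `log2(x+1)`-transformed,
  standardized features of the discovery split; penalty chosen on a grid
  (default 20 log-spaced values, C in [1e-3, 1e2]) by 5-fold stratified
  cross-validated deviance, folds seeded.  Selected features are ordered by
  |coefficient| (standardized scale).  The incremental curve refits an
  unpenalized logistic model on the top-k features and reports discovery and
  validation AUC for k = 1..K.  An all-zero selection raises a diagnostic
  error rather than returning an empty panel.

## Synthetic data generator

`simulate_dataset` emulates the aspects of TCGA-like isoform FPKM matrices
that stress this method; defaults define the standard verification scenario:

| parameter | default | meaning |
|---|---|---|
| subtypes | Basal, Her2, LumA, LumB, Normal | 5 groups |
| samples_per_subtype | 30 per split | discovery and validation drawn independently |
| n_genes / isoforms_per_gene | 1000, uniform on {1,2,3} | ~2000 isoforms, multi-isoform genes |
| baseline_mean, baseline_log_sd | 20 FPKM, 1.0 | lognormal spread of per-isoform baselines |
| dispersion_phi | 20 | Var = phi * mean (placeholder, not calibrated to any cohort) |
| zero_rate | 0.10 | structural zeros |
| outlier_rate, outlier_scale | 0.01, 50 | multiplicative spikes |
| n_specific | 20 per subtype (100 total) | planted single-subtype markers |
| n_coexpressed | 5 per pair (50 total) | planted pair markers |
| effect_fold | 8 | planted fold change |

Noise is Gamma(shape = mu/phi, scale = phi): continuous, non-negative, with
exactly the quasi-Poisson moment pair for any phi >= 1 (a negative-binomial
draw would be integer-valued; only the two moments are assumed downstream).
Zeros and outliers are applied after the draw.  Planted "specific" markers
multiply one subtype's mean by the fold; "coexpressed" markers multiply both
members of one pair.  `SimulationConfig.tcga_like()` provides an unequal
451-sample discovery cohort (81/30/209/111/20).

What the generator does **not** emulate — and hence what passing tests do not
show about real data: isoform-level correlation within genes, library-size or
batch effects, subtype label noise, mean-dependent dispersion trends, and
isoform-switching (planted effects are marginal per isoform).  Recovery rates
on real cohorts will differ.

## Numerical and design choices

- Wald p-values use the normal (T1) and chi-squared (T2) references; no
  small-sample t/F correction is applied.  At ~30 samples per group the tails
  are mildly anti-conservative (~2x at p ~ 1e-4), which the FDR gates absorb;
  at very small group sizes the normal reference is optimistic.
- PCA sample-outlier flagging codifies the usual visual check: samples whose
  top-2 PC scores (of log2(FPKM+1)) deviate from the component medians by
  more than k MAD (default k = 6) are flagged; the step is off by default.
- Biotype rule: coding → mRNA; non-coding and length > 200 nt → lncRNA; else
  small ncRNA.
- Ties and determinism: all rankings specify total orders; identical configs
  and seeds reproduce byte-identical outputs (pipeline manifests echo every
  default).
- Expression files are TSV (optionally gzipped), features x samples, 6
  significant digits on write; round-trips are lossless to ~1e-5 relative.

## Known limitations

- The exact robust weighting/dispersion/covariance combination is this
  package's own (declared above); other bounded-influence choices (Tukey
  bisquare, MAD scale) would give slightly different marker lists.
- T1's reference uses the unweighted mean of other-group coefficients; with
  extremely unbalanced cohorts the pooled option may be preferable.
- The FDR families are per subtype (or per pair) across features; switching
  to one global family changes discovery counts.
- Features are tested marginally; correlated isoforms of one gene are not
  jointly modeled, and panel selection inherits L1's instability among
  strongly correlated markers.
- Group sizes below ~10 leave the normal reference for T1 optimistic; the
  fold-change rescue path partially compensates but decisions at such sizes
  deserve skepticism.
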