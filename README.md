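# isospec

Systematic discovery of **subtype-specific** and **subtype co-expressed** RNA
isoforms from FPKM-like expression matrices, built around a robust
quasi-Poisson one-way ANOVA.

Molecular subtypes (e.g. the PAM50 intrinsic breast-cancer classes Basal,
Her2, Luminal A, Luminal B, Normal-like) are routinely characterized at the
gene level, but a gene's isoforms can behave very differently from each other
and from their gene.  `isospec` is for computational biologists who want to
screen an isoform-by-sample matrix for transcripts that mark exactly one
subtype — or exactly one pair of subtypes — and to turn those markers into
classifiers.  It works on any non-negative feature-by-sample matrix (isoform,
gene, or protein features).

## The statistical core

For each feature, a one-way ANOVA with quasi-Poisson moments is fitted on the
log scale:

```
E[y_i] = exp(beta_g(i)),   Var[y_i] = phi * E[y_i]
```

FPKM data carry many zeros and extreme outliers, so the fit is an M-estimator:
IWLS with Huber weights `psi_c(u)/u` on standardized Pearson residuals
`u = (y - mu) / sqrt(phi * mu)` (c = 1.345), a robust "Proposal 2" dispersion
estimate, and a sandwich covariance.  Being subtype-specific requires **two**
statistics per feature and subtype:

- **T1** — robust one-vs-rest t contrast: the target subtype's coefficient
  against the mean of the others (must be large and positive);
- **T2** — Wald chi-squared for joint equality of the *remaining* subtypes
  (must be small: the rest have to be indistinguishable).

Decisions combine Benjamini–Hochberg FDRs on both with a fold-change rescue
path: declare a feature subtype-specific when `FDR(T1) < 0.01` and
`FDR(T2) > 0.10`, or when `FDR(T1) < 0.01`, `FDR(T2) > 0.01` and the median
fold change exceeds 5.  The same machinery extends to subtype *pairs* (joint
over-expression in two subtypes, homogeneous rest, with a within-pair equality
gate).  Markers are ranked by one-vs-rest AUC (Mann–Whitney), compared against
their genes, and combined into panels via L1-penalized logistic regression
with cross-validated penalty selection.

A synthetic-data generator (`SimulationConfig` / `simulate_dataset`) emulates
TCGA-like isoform matrices — unequal subtype groups, multi-isoform genes,
overdispersed gamma noise with structural zeros and multiplicative outliers,
and planted markers at known fold change — so every stage can be verified
against ground truth.

## Worked example

```python
from isospec import (SimulationConfig, simulate_dataset, run_specificity,
                     run_coexpression, top_specific, fit_l1_panel,
                     incremental_panel_auc)

cfg = SimulationConfig(seed=42)      # 5 subtypes x 30 samples/split, ~2000 isoforms
x, samples, annotation, truth = simulate_dataset(cfg)

res = run_specificity(x, samples)    # discovery split only
print(int(res.decision.sum()))       # 109 feature x subtype decisions
print(top_specific(res, n=3).head(3)[["feature_id", "subtype", "t1", "fdr1", "fdr2"]])
```

```
feature_id subtype        t1          fdr1     fdr2
  G00673.1   Basal 32.357417 2.160382e-226 0.834693
  G00018.1   Basal 22.972410 5.807534e-114 0.954559
  G00568.1   Basal 22.526528 1.129356e-109 0.994580
```

`G00673.1` is over-expressed ~9-fold in Basal samples (t1 = 32, FDR(T1) ≈
2e-226) while the other four subtypes are indistinguishable on it (FDR(T2) =
0.83) — the signature of a subtype-specific isoform.  With this seed the
screen returns 109 decisions, all via the primary rule path, recovering the
100 planted markers with a handful of false calls; `run_coexpression(x,
samples)` likewise returns 48 pair decisions against 50 planted pair markers.

Panels for a hard two-class separation:

```python
cfg2 = SimulationConfig(subtype_names=("LumA", "LumB"), samples_per_subtype=(100, 100),
                        n_genes=250, n_specific=(0, 5), n_coexpressed=0, seed=42)
px, psamp, _, _ = simulate_dataset(cfg2)
panel = fit_l1_panel(px, psamp, ("LumA", "LumB"), seed=42)
for k, auc_d, auc_v in incremental_panel_auc(panel, px, psamp, max_k=5):
    print(f"k={k}: AUC discovery {auc_d:.3f} validation {auc_v:.3f}")
```

```
k=1: AUC discovery 0.867 validation 0.849
k=2: AUC discovery 0.953 validation 0.939
k=3: AUC discovery 0.975 validation 0.971
k=4: AUC discovery 0.986 validation 0.979
k=5: AUC discovery 0.994 validation 0.983
```

The top-5 panel separates the two luminal-like classes with held-out AUC 0.98;
all five planted markers rank at the top of the selection.

## Command line

```
isospec simulate --seed 1 --out sim/
isospec specificity --expression sim/expression.tsv --samples sim/samples.tsv --out spec.tsv
isospec coexpression --expression sim/expression.tsv --samples sim/samples.tsv --out coex.tsv
isospec panel --expression sim/expression.tsv --samples sim/samples.tsv --pair LumA,LumB --out panel.tsv
isospec run --simulate --seed 1 --out run/        # full pipeline + manifest.json
```

All I/O is plain TSV (features x samples with a header row of sample ids;
annotation tables with `isoform_id, gene_id, is_coding, length_nt`; sample
tables with `sample_id, subtype, split`).  Threshold flags `--fdr1
--fdr2-primary --fdr2-rescue --fc` default to 0.01 / 0.10 / 0.01 / 5.

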