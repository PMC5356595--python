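"""Subtype-specificity testing: T1/T2 statistics, FDR gates and decisions.

A feature is subtype-specific when it is significantly over-expressed in one
subtype (large one-vs-rest robust t, T1) while the remaining subtypes are
statistically indistinguishable on it (small joint homogeneity chi-squared,
T2).  Decisions combine Benjamini-Hochberg FDRs on both statistics with a
fold-change rescue path:

* primary: FDR(T1) < 0.01 and FDR(T2) > 0.10, over-expression only;
* rescue:  FDR(T1) < 0.01, FDR(T2) > 0.01 and median fold change > 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import ExpressionMatrix, SampleAnnotation, ValidationError
from .robust_qp import BatchQPFit, FitOptions, QPFit, fit_qp_batch, wald_contrast

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Decision-rule configuration (defaults are the published gates)."""

    fdr1: float = 0.01
    fdr2_primary: float = 0.10
    fdr2_rescue: float = 0.01
    fold_change: float = 5.0
    pseudocount: float = 0.01  # FPKM added to medians before forming ratios


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _t1_contrast(G: int, j: int, counts: np.ndarray | None = None) -> np.ndarray:
    """One-vs-rest contrast: +1 on the target, rest averaged (optionally n-weighted)."""
    c = np.zeros(G)
    c[j] = 1.0
    others = np.arange(G) != j
    if counts is None:
        c[others] = -1.0 / (G - 1)
    else:
        c[others] = -counts[others] / counts[others].sum()
    return c


def _t_and_p(est: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    se = np.sqrt(np.maximum(var, 0.0))
    t = np.zeros_like(est)
    nonzero = se > 0
    t[nonzero] = est[nonzero] / se[nonzero]
    # zero se with nonzero estimate: infinitely confident contrast
    t[(~nonzero) & (est != 0)] = np.sign(est[(~nonzero) & (est != 0)]) * np.inf
    p = 2.0 * stats.norm.sf(np.abs(t))
    return t, p


def t1_statistic(fit: QPFit, target: str, reference: str = "unweighted") -> tuple[float, float]:
    """Signed robust one-vs-rest t for ``target`` with its two-sided normal p.

    Positive values mean the target subtype is over-expressed relative to the
    (unweighted by default) average of the other subtypes.
    """
    if target not in fit.group_labels:
        raise ValidationError(f"unknown target subtype {target!r}")
    if len(fit.group_labels) < 2:
        raise ValidationError("need at least 2 groups for T1")
    j = fit.group_labels.index(target)
    counts = fit.group_counts.astype(float) if reference == "pooled" else None
    est, se = wald_contrast(fit, _t1_contrast(len(fit.group_labels), j, counts))
    t, p = _t_and_p(np.array([est]), np.array([se**2]))
    return float(t[0]), float(p[0])


def _homogeneity_batch(beta: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Wald chi-squared for joint equality of columns, diagonal covariance.

    With diagonal covariance the quadratic form (C b)'(C S C')^{-1}(C b)
    reduces to the precision-weighted dispersion around the weighted mean.
    """
    if beta.shape[1] < 2:
        return np.zeros(beta.shape[0]), np.zeros(beta.shape[0])
    w = 1.0 / np.maximum(var, 1e-300)
    bbar = (w * beta).sum(axis=1) / w.sum(axis=1)
    t2 = (w * (beta - bbar[:, None]) ** 2).sum(axis=1)
    p = stats.chi2.sf(t2, df=beta.shape[1] - 1)
    p[t2 == 0] = 1.0
    return t2, p


def t2_statistic(fit: QPFit, excluded: set[str] | Sequence[str]) -> tuple[float, int, float]:
    """Joint homogeneity chi-squared of the subtypes not in ``excluded``."""
    excluded = set(excluded)
    keep = [i for i, g in enumerate(fit.group_labels) if g not in excluded]
    if len(keep) < 2:
        raise ValidationError("fewer than 2 subtypes remain for T2")
    var = np.diag(fit.cov_beta)[keep]
    t2, p = _homogeneity_batch(fit.beta[None, keep], var[None, :])
    return float(t2[0]), len(keep) - 1, float(p[0])


def median_fold_change(
    values: Sequence[float],
    target_mask: Sequence[bool],
    pseudocount: float = 0.01,
) -> float:
    """(median of target samples + pc) / (median of pooled rest + pc)."""
    values = np.asarray(values, dtype=float)
    mask = np.asarray(target_mask, dtype=bool)
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValidationError("both target and rest groups must be non-empty")
    return float(
        (np.median(values[mask]) + pseudocount) / (np.median(values[~mask]) + pseudocount)
    )


def decide_specific(
    fdr1: float,
    fdr2: float,
    fold_change: float,
    t1: float,
    thresholds: Thresholds | None = None,
) -> tuple[bool, str]:
    """Apply the two-path decision rule; returns (decision, rule_path).

    The primary path requires a quiet rest (large FDR on T2); the rescue path
    tolerates mild rest heterogeneity when the median fold change is large.
    The primary path is reported when both hold.
    """
    th = thresholds or Thresholds()
    if t1 > 0 and fdr1 < th.fdr1:
        if fdr2 > th.fdr2_primary:
            return True, "primary"
        if fdr2 > th.fdr2_rescue and fold_change > th.fold_change:
            return True, "rescue"
    return False, "none"


def _decide_batch(fdr1, fdr2, fc, t1, th: Thresholds):
    gate = (t1 > 0) & (fdr1 < th.fdr1)
    primary = gate & (fdr2 > th.fdr2_primary)
    rescue = gate & ~primary & (fdr2 > th.fdr2_rescue) & (fc > th.fold_change)
    decision = primary | rescue
    path = np.where(primary, "primary", np.where(rescue, "rescue", "none"))
    return decision, path


def run_specificity(
    x: ExpressionMatrix,
    samples: SampleAnnotation,
    thresholds: Thresholds | None = None,
    fit_options: FitOptions | None = None,
    split: str = "discovery",
    reference: str = "unweighted",
    fit: BatchQPFit | None = None,
) -> pd.DataFrame:
    """Full one-vs-rest screen: one robust fit per feature, T1/T2 per subtype.

    FDRs are adjusted across features separately within each target subtype
    (separately for the T1 and T2 p-value families).  Non-converged fits are
    excluded from testing and listed in ``result.attrs["excluded_features"]``.
    Only samples of the requested ``split`` are used.
    """
    th = thresholds or Thresholds()
    sample_ids = samples.samples_in_split(split)
    if not sample_ids:
        raise ValidationError(f"no samples in split {split!r}")
    xs = x.subset_samples(sample_ids)
    groups = samples.labels_for(sample_ids)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValidationError("need at least 2 subtypes")
    if fit is None:
        fit = fit_qp_batch(xs.values, groups, fit_options, feature_ids=xs.feature_ids)

    keep = fit.converged
    excluded = [f for f, ok in zip(fit.feature_ids, keep) if not ok]
    if excluded:
        logger.warning("excluding %d non-converged features", len(excluded))
    beta = fit.beta[keep]
    var = fit.var_beta[keep]
    feats = np.array(fit.feature_ids)[keep]
    vals = xs.values[keep]
    G = len(fit.group_labels)
    counts = np.array([(groups == g).sum() for g in fit.group_labels], dtype=float)

    frames = []
    for j, target in enumerate(fit.group_labels):
        cvec = _t1_contrast(G, j, counts if reference == "pooled" else None)
        est = beta @ cvec
        var_c = var @ cvec**2
        t1, p1 = _t_and_p(est, var_c)
        rest = [k for k in range(G) if k != j]
        t2, p2 = _homogeneity_batch(beta[:, rest], var[:, rest])
        mask = groups == target
        fc = (np.median(vals[:, mask], axis=1) + th.pseudocount) / (
            np.median(vals[:, ~mask], axis=1) + th.pseudocount
        )
        fdr1 = bh_fdr(p1)
        fdr2 = bh_fdr(p2)
        decision, path = _decide_batch(fdr1, fdr2, fc, t1, th)
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": feats,
                    "subtype": target,
                    "t1": t1,
                    "p1": p1,
                    "fdr1": fdr1,
                    "t2": t2,
                    "df2": G - 2,
                    "p2": p2,
                    "fdr2": fdr2,
                    "fold_change": fc,
                    "decision": decision,
                    "rule_path": path,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["feature_id", "subtype"], kind="mergesort", ignore_index=True
    )
    out.attrs["excluded_features"] = excluded
    out.attrs["split"] = split
    return out


def top_specific(results: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Top-n decided features per subtype: fdr1 ascending, |t1| descending, id."""
    dec = results[results["decision"]].copy()
    dec["abs_t1"] = dec["t1"].abs()
    dec = dec.sort_values(
        ["subtype", "fdr1", "abs_t1", "feature_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return dec.groupby("subtype", group_keys=False).head(n).drop(columns="abs_t1").reset_index(drop=True)
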