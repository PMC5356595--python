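"""Pairwise subtype co-expression: joint over-expression in two subtypes.

Extension of the one-vs-rest screen: for every unordered subtype pair, T1
contrasts the mean of the pair's log-scale coefficients against the mean of
the remaining subtypes, and T2 jointly tests homogeneity of the remaining
subtypes.  An optional within-pair Wald equality gate (on by default) demands
that the two pair members are themselves indistinguishable, which keeps
single-subtype markers from leaking into pair calls.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from .data_model import ExpressionMatrix, SampleAnnotation, ValidationError
from .robust_qp import BatchQPFit, FitOptions, fit_qp_batch
from .specificity import Thresholds, _homogeneity_batch, _t_and_p, bh_fdr

logger = logging.getLogger(__name__)


def run_coexpression(
    x: ExpressionMatrix,
    samples: SampleAnnotation,
    thresholds: Thresholds | None = None,
    fit_options: FitOptions | None = None,
    split: str = "discovery",
    within_pair_gate: bool = True,
    within_pair_alpha: float = 0.05,
    fit: BatchQPFit | None = None,
) -> pd.DataFrame:
    """Screen every unordered subtype pair for joint over-expression.

    Decision: FDR(T1) < fdr1 and FDR(T2) > fdr2_primary and T1 > 0, plus the
    within-pair equality check (Wald p >= ``within_pair_alpha``) when enabled.
    FDRs are adjusted across features within each pair family.  Results are
    identical for (A, B) and (B, A); pairs are reported with members in sorted
    order.
    """
    th = thresholds or Thresholds()
    sample_ids = samples.samples_in_split(split)
    if not sample_ids:
        raise ValidationError(f"no samples in split {split!r}")
    xs = x.subset_samples(sample_ids)
    groups = samples.labels_for(sample_ids)
    if len(np.unique(groups)) < 3:
        raise ValidationError("co-expression needs at least 3 subtypes")
    if fit is None:
        fit = fit_qp_batch(xs.values, groups, fit_options, feature_ids=xs.feature_ids)

    keep = fit.converged
    excluded = [f for f, ok in zip(fit.feature_ids, keep) if not ok]
    if excluded:
        logger.warning("excluding %d non-converged features", len(excluded))
    beta = fit.beta[keep]
    var = fit.var_beta[keep]
    feats = np.array(fit.feature_ids)[keep]
    G = len(fit.group_labels)

    frames = []
    for a, b in itertools.combinations(range(G), 2):
        rest = [k for k in range(G) if k not in (a, b)]
        cvec = np.zeros(G)
        cvec[[a, b]] = 0.5
        cvec[rest] = -1.0 / len(rest)
        t1, p1 = _t_and_p(beta @ cvec, var @ cvec**2)
        if len(rest) >= 2:
            t2, p2 = _homogeneity_batch(beta[:, rest], var[:, rest])
            df2 = len(rest) - 1
        else:  # a single remaining subtype is vacuously homogeneous
            t2 = np.zeros(len(feats))
            p2 = np.ones(len(feats))
            df2 = 0
        wp_t, wp_p = _t_and_p(beta[:, a] - beta[:, b], var[:, a] + var[:, b])
        fdr1 = bh_fdr(p1)
        fdr2 = bh_fdr(p2)
        decision = (t1 > 0) & (fdr1 < th.fdr1) & (fdr2 > th.fdr2_primary)
        if within_pair_gate:
            decision &= wp_p >= within_pair_alpha
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": feats,
                    "subtype_a": fit.group_labels[a],
                    "subtype_b": fit.group_labels[b],
                    "t1": t1,
                    "p1": p1,
                    "fdr1": fdr1,
                    "t2": t2,
                    "df2": df2,
                    "p2": p2,
                    "fdr2": fdr2,
                    "within_pair_p": wp_p,
                    "decision": decision,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["feature_id", "subtype_a", "subtype_b"], kind="mergesort", ignore_index=True
    )
    out.attrs["excluded_features"] = excluded
    out.attrs["split"] = split
    return out


def top_coexpressed(results: pd.DataFrame, n: int = 25) -> pd.DataFrame:
    """Best-n decided features per pair, ranked by |t1| descending."""
    dec = results[results["decision"]].copy()
    dec["abs_t1"] = dec["t1"].abs()
    dec = dec.sort_values(
        ["subtype_a", "subtype_b", "abs_t1", "feature_id"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return (
        dec.groupby(["subtype_a", "subtype_b"], group_keys=False)
        .head(n)
        .drop(columns="abs_t1")
        .reset_index(drop=True)
    )
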