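"""End-to-end orchestration: simulate/load -> fit -> specificity -> coexpression -> classify.

Every run writes its stage outputs as TSV plus a JSON manifest (full config
echo, seed, package version, per-stage feature counts, convergence summary and
wall times) so a run can be reproduced exactly from the manifest alone.
Validation samples are never read before the classification evaluation stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import (
    PanelSelectionError,
    compare_isoform_gene_auc,
    fit_l1_panel,
    incremental_panel_auc,
    marker_auc_table,
)
from .coexpression import run_coexpression
from .data_model import (
    SampleAnnotation,
    ValidationError,
    aggregate_gene_level,
    flag_pca_outliers,
    read_expression,
    read_sample_annotation,
    read_transcript_annotation,
    write_expression,
    write_sample_annotation,
    write_transcript_annotation,
)
from .robust_qp import FitOptions, fit_qp_batch
from .specificity import Thresholds, run_specificity
from .synthetic import SimulationConfig, simulate_dataset, truth_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs either as TSV paths or a simulation config (exactly one)."""

    expression_path: str | None = None
    sample_annotation_path: str | None = None
    transcript_annotation_path: str | None = None
    simulation: SimulationConfig | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    fit_options: FitOptions = field(default_factory=FitOptions)
    panel_pair: tuple[str, str] = ("LumA", "LumB")
    seed: int = 0
    cv_folds: int = 5
    penalty_grid: list[float] | None = None
    flag_outliers: bool = False
    outlier_mad_multiplier: float = 6.0
    output_dir: str = "isospec_run"

    def validate(self) -> None:
        have_paths = self.expression_path is not None
        if have_paths == (self.simulation is not None):
            raise ValidationError("provide either input paths or a simulation config")
        if have_paths and not (self.sample_annotation_path and self.transcript_annotation_path):
            raise ValidationError("sample and transcript annotation paths are both required")
        th = self.thresholds
        for v in (th.fdr1, th.fdr2_primary, th.fdr2_rescue):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"FDR threshold {v} outside [0, 1]")
        if th.fold_change <= 1:
            raise ValidationError("fold-change threshold must be > 1")


def _asdict(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    if isinstance(obj, dict):
        return {str(k): _asdict(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": _asdict(cfg),
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s started", name)
        return t0

    def done(name, t0, **info):
        manifest["stages"][name] = {"wall_time_s": round(time.perf_counter() - t0, 3), **info}
        logger.info("stage %s done: %s", name, info)

    # --- inputs ------------------------------------------------------------
    t0 = stage("inputs")
    if cfg.simulation is not None:
        x, samples, annotation, truth = simulate_dataset(cfg.simulation)
        write_expression(x, out / "expression.tsv")
        write_sample_annotation(samples, out / "samples.tsv")
        write_transcript_annotation(annotation, out / "transcripts.tsv")
        truth_frame(truth).to_csv(out / "truth.tsv", sep="\t", index=False)
    else:
        x = read_expression(cfg.expression_path)
        samples = read_sample_annotation(cfg.sample_annotation_path)
        annotation = read_transcript_annotation(cfg.transcript_annotation_path)
    done("inputs", t0, n_features=len(x.feature_ids), n_samples=len(x.sample_ids))

    if cfg.flag_outliers:
        t0 = stage("pca_outliers")
        flagged = flag_pca_outliers(x, mad_multiplier=cfg.outlier_mad_multiplier)
        if flagged:
            keep = [s for s in x.sample_ids if s not in flagged]
            x = x.subset_samples(keep)
            samples = SampleAnnotation(samples.frame[~samples.frame["sample_id"].isin(flagged)])
            logger.info("dropped %d PCA-flagged samples: %s", len(flagged), sorted(flagged))
        done("pca_outliers", t0, flagged=sorted(flagged))

    # --- robust fits on the discovery split --------------------------------
    t0 = stage("fit")
    disc_ids = samples.samples_in_split("discovery")
    xd = x.subset_samples(disc_ids)
    groups = samples.labels_for(disc_ids)
    fit = fit_qp_batch(xd.values, groups, cfg.fit_options, feature_ids=xd.feature_ids)
    fit.to_frame().to_csv(out / "fit.tsv", sep="\t", index=False, float_format="%.6g")
    done(
        "fit",
        t0,
        n_features=len(fit.feature_ids),
        n_converged=int(fit.converged.sum()),
        n_nonconverged=int((~fit.converged).sum()),
        nonconverged_features=[f for f, ok in zip(fit.feature_ids, fit.converged) if not ok],
    )

    t0 = stage("specificity")
    spec = run_specificity(x, samples, cfg.thresholds, cfg.fit_options, fit=fit)
    spec.to_csv(out / "specificity.tsv", sep="\t", index=False, float_format="%.6g")
    done(
        "specificity",
        t0,
        n_decisions=int(spec["decision"].sum()),
        n_primary=int((spec["rule_path"] == "primary").sum()),
        n_rescue=int((spec["rule_path"] == "rescue").sum()),
    )

    t0 = stage("coexpression")
    n_groups = len(np.unique(groups))
    if n_groups >= 3:
        coex = run_coexpression(x, samples, cfg.thresholds, cfg.fit_options, fit=fit)
        coex.to_csv(out / "coexpression.tsv", sep="\t", index=False, float_format="%.6g")
        done("coexpression", t0, n_decisions=int(coex["decision"].sum()))
    else:
        coex = None
        done("coexpression", t0, skipped="fewer than 3 subtypes")

    # --- classification: per-marker AUC, isoform vs gene, panel -------------
    t0 = stage("classify")
    decided = sorted(spec.loc[spec["decision"], "feature_id"].unique())
    if decided:
        iso_auc = marker_auc_table(x, samples, level="isoform", feature_ids=decided)
        gene_x = aggregate_gene_level(x, annotation)
        gene_auc = marker_auc_table(gene_x, samples, level="gene")
        delta = compare_isoform_gene_auc(iso_auc, gene_auc, annotation)
        iso_auc.to_csv(out / "marker_auc.tsv", sep="\t", index=False, float_format="%.6g")
        delta.to_csv(out / "isoform_vs_gene_auc.tsv", sep="\t", index=False, float_format="%.6g")
        done(
            "classify",
            t0,
            n_markers=len(decided),
            frac_isoform_better=delta.attrs.get("frac_isoform_better_discovery"),
        )
    else:
        done("classify", t0, skipped="no decided markers")

    t0 = stage("panel")
    a, b = cfg.panel_pair
    pair_markers = sorted(
        spec.loc[spec["decision"] & spec["subtype"].isin([a, b]), "feature_id"].unique()
    )
    if len(pair_markers) >= 2:
        try:
            panel = fit_l1_panel(
                x.subset_features(pair_markers),
                samples,
                (a, b),
                penalty_grid=cfg.penalty_grid,
                seed=cfg.seed,
                folds=cfg.cv_folds,
            )
            curve = incremental_panel_auc(panel, x, samples)
            pd.DataFrame(
                {
                    "feature_id": panel.selected_features,
                    "coefficient": panel.coefficients,
                    "rank": np.arange(1, len(panel.selected_features) + 1),
                }
            ).to_csv(out / "panel.tsv", sep="\t", index=False, float_format="%.6g")
            pd.DataFrame(curve, columns=["k", "auc_discovery", "auc_validation"]).to_csv(
                out / "panel_auc_curve.tsv", sep="\t", index=False, float_format="%.6g"
            )
            done(
                "panel",
                t0,
                n_selected=len(panel.selected_features),
                penalty_strength=panel.penalty_strength,
                full_panel_auc_validation=curve[-1][2],
            )
        except PanelSelectionError as exc:
            done("panel", t0, skipped=str(exc))
    else:
        done("panel", t0, skipped=f"fewer than 2 markers specific to {a} or {b}")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
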