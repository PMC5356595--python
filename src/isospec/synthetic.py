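"""Synthetic TCGA-like isoform expression datasets with known planted truth.

The generator emulates the features of bulk tumor FPKM matrices that drive the
design of the robust test: five unequal subtype groups, multi-isoform genes,
overdispersed non-negative expression (Var = phi * mean), pervasive structural
zeros, occasional extreme multiplicative outliers, and planted single-subtype
and pairwise co-expression patterns at a controlled fold change.  Every draw
is reproducible from the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionMatrix, SampleAnnotation, TranscriptAnnotation, ValidationError

DEFAULT_SUBTYPES = ("Basal", "Her2", "LumA", "LumB", "Normal")


@dataclass
class SimulationConfig:
    """Generator parameters.

    ``samples_per_subtype`` applies to each split (discovery and validation
    are generated independently with the same planted truth).  ``n_specific``
    is the number of planted single-subtype markers *per subtype* and
    ``n_coexpressed`` the number of planted markers *per subtype pair*.
    """

    subtype_names: Sequence[str] = DEFAULT_SUBTYPES
    samples_per_subtype: Sequence[int] = (30, 30, 30, 30, 30)
    n_genes: int = 1000
    isoforms_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 1 / 3, 2: 1 / 3, 3: 1 / 3}
    )
    baseline_mean: float = 20.0  # FPKM scale
    baseline_log_sd: float = 1.0  # lognormal spread of per-isoform baselines
    dispersion_phi: float = 20.0  # quasi-Poisson variance inflation, Var = phi*mean
    zero_rate: float = 0.10
    outlier_rate: float = 0.01
    outlier_scale: float = 50.0
    n_specific: int | Sequence[int] = 20  # scalar, or one count per subtype
    n_coexpressed: int | Sequence[int] = 5  # scalar, or one count per pair
    effect_fold: float = 8.0
    frac_coding: float = 0.8
    seed: int = 0

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_names)

    def specific_counts(self) -> list[int]:
        if isinstance(self.n_specific, int):
            return [self.n_specific] * self.n_subtypes
        return list(self.n_specific)

    def coexpressed_counts(self) -> list[int]:
        n_pairs = self.n_subtypes * (self.n_subtypes - 1) // 2
        if isinstance(self.n_coexpressed, int):
            return [self.n_coexpressed] * n_pairs
        return list(self.n_coexpressed)

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise ValidationError("need at least 2 subtypes")
        if len(self.samples_per_subtype) != self.n_subtypes:
            raise ValidationError("samples_per_subtype length must match subtype_names")
        if any(n < 2 for n in self.samples_per_subtype):
            raise ValidationError("each subtype needs >= 2 samples per split")
        for rate in (self.zero_rate, self.outlier_rate, self.frac_coding):
            if not 0.0 <= rate <= 1.0:
                raise ValidationError(f"rate {rate} outside [0, 1]")
        if self.effect_fold <= 1.0:
            raise ValidationError("effect_fold must be > 1")
        if self.dispersion_phi < 1.0:
            raise ValidationError("dispersion_phi must be >= 1")
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be positive")
        probs = np.array(list(self.isoforms_per_gene.values()), dtype=float)
        if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValidationError("isoforms_per_gene probabilities must be >= 0 and sum to 1")

    @classmethod
    def tcga_like(cls, **overrides) -> "SimulationConfig":
        """Preset mimicking a 451-sample discovery cohort with unequal subtypes."""
        defaults = dict(samples_per_subtype=(81, 30, 209, 111, 20))
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth pattern of one isoform: specific, coexpressed or null."""

    isoform_id: str
    pattern: str  # "specific" | "coexpressed" | "null"
    subtypes: tuple[str, ...]  # () for null, (s,) for specific, (a, b) for pairs
    effect_fold: float


def truth_frame(truth: Sequence[PlantedTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [(t.isoform_id, t.pattern, ",".join(t.subtypes), t.effect_fold) for t in truth],
        columns=["isoform_id", "pattern", "subtypes", "effect_fold"],
    )


def _draw_expression(
    rng: np.random.Generator,
    means: np.ndarray,  # features x samples
    phi: float,
    zero_rate: float,
    outlier_rate: float,
    outlier_scale: float,
) -> np.ndarray:
    # Gamma(shape=mu/phi, scale=phi): mean mu, variance phi*mu, continuous >= 0.
    values = rng.gamma(shape=means / phi, scale=phi)
    if zero_rate > 0:
        values[rng.random(means.shape) < zero_rate] = 0.0
    if outlier_rate > 0:
        values[rng.random(means.shape) < outlier_rate] *= outlier_scale
    return values


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, list[TranscriptAnnotation], list[PlantedTruth]]:
    """Generate (expression, sample annotation, transcript annotation, truth).

    Planted "specific" isoforms have their mean multiplied by ``effect_fold``
    in one subtype; planted "coexpressed" isoforms in both members of one
    subtype pair; all other isoforms are null (identical group means).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    subtypes = list(cfg.subtype_names)
    pairs = list(itertools.combinations(subtypes, 2))

    # --- transcript annotation -------------------------------------------
    k_choices = np.array(list(cfg.isoforms_per_gene.keys()))
    k_probs = np.array(list(cfg.isoforms_per_gene.values()), dtype=float)
    iso_counts = rng.choice(k_choices, size=cfg.n_genes, p=k_probs / k_probs.sum())
    annotation: list[TranscriptAnnotation] = []
    for g, k in enumerate(iso_counts):
        gene = f"G{g:05d}"
        for j in range(k):
            coding = bool(rng.random() < cfg.frac_coding)
            if coding:
                length = int(rng.integers(500, 6000))
            else:
                # mix of lncRNA (>200 nt) and small ncRNA (<=200 nt)
                length = int(rng.integers(300, 3000)) if rng.random() < 0.8 else int(rng.integers(50, 201))
            annotation.append(TranscriptAnnotation(f"{gene}.{j + 1}", gene, coding, length))
    iso_ids = [a.isoform_id for a in annotation]
    n_iso = len(iso_ids)

    spec_counts = cfg.specific_counts()
    coex_counts = cfg.coexpressed_counts()
    if len(spec_counts) != len(subtypes) or len(coex_counts) != len(pairs):
        raise ValidationError("planted count lists must match subtype/pair counts")
    n_planted = sum(spec_counts) + sum(coex_counts)
    if n_planted > n_iso:
        raise ValidationError(f"{n_planted} planted markers exceed {n_iso} isoforms")

    # --- planted truth ----------------------------------------------------
    planted_idx = rng.choice(n_iso, size=n_planted, replace=False)
    truth: list[PlantedTruth] = [
        PlantedTruth(iso, "null", (), 1.0) for iso in iso_ids
    ]
    cursor = 0
    for s, k in zip(subtypes, spec_counts):
        for _ in range(k):
            i = planted_idx[cursor]
            truth[i] = PlantedTruth(iso_ids[i], "specific", (s,), cfg.effect_fold)
            cursor += 1
    for pair, k in zip(pairs, coex_counts):
        for _ in range(k):
            i = planted_idx[cursor]
            truth[i] = PlantedTruth(iso_ids[i], "coexpressed", pair, cfg.effect_fold)
            cursor += 1

    # --- group means ------------------------------------------------------
    base = cfg.baseline_mean * rng.lognormal(
        mean=-0.5 * cfg.baseline_log_sd**2, sigma=cfg.baseline_log_sd, size=n_iso
    )
    group_means = np.tile(base[:, None], (1, len(subtypes)))  # features x subtypes
    col = {s: j for j, s in enumerate(subtypes)}
    for i, t in enumerate(truth):
        for s in t.subtypes:
            group_means[i, col[s]] *= cfg.effect_fold

    # --- samples, both splits independently -------------------------------
    sample_ids: list[str] = []
    sample_rows: list[tuple[str, str, str]] = []
    blocks: list[np.ndarray] = []
    for split in ("discovery", "validation"):
        for j, s in enumerate(subtypes):
            n = cfg.samples_per_subtype[j]
            ids = [f"{split[:4].upper()}_{s}_{k:03d}" for k in range(n)]
            sample_ids.extend(ids)
            sample_rows.extend((sid, s, split) for sid in ids)
            means = np.tile(group_means[:, [j]], (1, n))
            blocks.append(
                _draw_expression(
                    rng, means, cfg.dispersion_phi, cfg.zero_rate, cfg.outlier_rate, cfg.outlier_scale
                )
            )
    values = np.concatenate(blocks, axis=1)

    x = ExpressionMatrix(iso_ids, sample_ids, values)
    samples = SampleAnnotation(pd.DataFrame(sample_rows, columns=["sample_id", "subtype", "split"]))
    return x, samples, annotation, truth
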