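"""Core data containers, TSV readers/writers, biotype rules and gene-level aggregation.

The package works on dense, non-negative feature-by-sample expression matrices
(FPKM-like units).  Features may be RNA isoforms, genes (isoform sums) or any
other non-negative feature such as protein abundances; nothing downstream
assumes more than non-negativity and a group label per sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


class IsospecError(Exception):
    """Base class for structured errors raised by this package."""


class ValidationError(IsospecError):
    """An input violated a container invariant (duplicate id, negative value, ...)."""


class MissingAnnotationError(IsospecError):
    """Features present in an expression matrix lack annotation records."""

    def __init__(self, missing: Sequence[str]):
        self.missing = list(missing)
        preview = ", ".join(self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"{len(self.missing)} features missing annotation: {preview}{more}")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense non-negative feature-by-sample matrix with string identifiers.

    Invariants enforced on construction: finite non-negative values, unique
    feature and sample ids, and a value shape of (n_features, n_samples).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"({len(self.feature_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at feature {self.feature_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )
        if np.any(self.values < 0):
            r, c = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative value {self.values[r, c]} at feature "
                f"{self.feature_ids[r]!r}, sample {self.sample_ids[c]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return ExpressionMatrix(list(self.feature_ids), list(sample_ids), self.values[:, idx])

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return ExpressionMatrix(list(feature_ids), list(self.sample_ids), self.values[idx, :])

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]


@dataclass(frozen=True)
class TranscriptAnnotation:
    """One isoform's annotation: gene membership, coding status, length in nt."""

    isoform_id: str
    gene_id: str
    is_coding: bool
    length_nt: int

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValidationError(f"length_nt must be >= 1, got {self.length_nt} for {self.isoform_id!r}")


LNCRNA_MIN_LENGTH_NT = 200  # non-coding transcripts longer than this are lncRNA


def classify_biotype(ann: TranscriptAnnotation) -> str:
    """Return the biotype class of one transcript: 'mRNA', 'lncRNA' or 'small_ncRNA'.

    Coding transcripts are mRNA regardless of length; non-coding transcripts
    longer than 200 nt are lncRNA, the rest small_ncRNA.
    """
    if ann.is_coding:
        return "mRNA"
    return "lncRNA" if ann.length_nt > LNCRNA_MIN_LENGTH_NT else "small_ncRNA"


@dataclass
class SampleAnnotation:
    """Sample metadata table: subtype label and discovery/validation split."""

    frame: pd.DataFrame  # columns: sample_id, subtype, split

    def __post_init__(self) -> None:
        required = {"sample_id", "subtype", "split"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"sample annotation missing columns: {sorted(missing)}")
        self.frame = self.frame.reset_index(drop=True)
        _check_unique(list(self.frame["sample_id"].astype(str)), "sample")
        bad = set(self.frame["split"]) - {"discovery", "validation"}
        if bad:
            raise ValidationError(f"unknown split labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"].astype(str))

    def subtypes(self) -> list[str]:
        return sorted(self.frame["subtype"].astype(str).unique())

    def samples_in_split(self, split: str) -> list[str]:
        return list(self.frame.loc[self.frame["split"] == split, "sample_id"].astype(str))

    def subtype_of(self) -> dict[str, str]:
        return dict(zip(self.frame["sample_id"].astype(str), self.frame["subtype"].astype(str)))

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        mapping = self.subtype_of()
        try:
            return np.array([mapping[s] for s in sample_ids])
        except KeyError as exc:
            raise ValidationError(f"sample without annotation record: {exc.args[0]!r}") from exc


# ---------------------------------------------------------------------------
# TSV I/O.  Expression: feature ids in column 1, header row = sample ids.
# ---------------------------------------------------------------------------

def read_expression(path: str | Path, sep: str = "\t") -> ExpressionMatrix:
    """Read a feature-by-sample expression TSV (gzip accepted via suffix)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().to_numpy().any():
        r, c = np.argwhere(body.isna().to_numpy())[0]
        raise ValidationError(
            f"non-numeric value at feature {df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    return ExpressionMatrix.from_frame(body)


def write_expression(x: ExpressionMatrix, path: str | Path, sep: str = "\t", sig_digits: int = 6) -> None:
    """Write an expression matrix as TSV with `sig_digits` significant digits."""
    x.to_frame().to_csv(path, sep=sep, float_format=f"%.{sig_digits}g", index_label="feature_id")


def read_transcript_annotation(path: str | Path, sep: str = "\t") -> list[TranscriptAnnotation]:
    df = pd.read_csv(path, sep=sep)
    records = [
        TranscriptAnnotation(str(r.isoform_id), str(r.gene_id), bool(int(r.is_coding)), int(r.length_nt))
        for r in df.itertuples(index=False)
    ]
    _check_unique([r.isoform_id for r in records], "isoform")
    return records


def write_transcript_annotation(records: Iterable[TranscriptAnnotation], path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame(
        [(r.isoform_id, r.gene_id, int(r.is_coding), r.length_nt) for r in records],
        columns=["isoform_id", "gene_id", "is_coding", "length_nt"],
    ).to_csv(path, sep=sep, index=False)


def read_sample_annotation(path: str | Path, sep: str = "\t") -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep=sep, dtype=str))


def write_sample_annotation(s: SampleAnnotation, path: str | Path, sep: str = "\t") -> None:
    s.frame.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Gene-level aggregation and PCA-based sample outlier flagging
# ---------------------------------------------------------------------------

def aggregate_gene_level(x: ExpressionMatrix, ann: Iterable[TranscriptAnnotation]) -> ExpressionMatrix:
    """Sum isoform rows into gene rows (gene-level FPKM = sum of isoform FPKM).

    Gene rows appear in order of first appearance among the features; sample
    order is preserved.  Raises :class:`MissingAnnotationError` listing every
    feature without an annotation record.
    """
    gene_of = {a.isoform_id: a.gene_id for a in ann}
    missing = [f for f in x.feature_ids if f not in gene_of]
    if missing:
        raise MissingAnnotationError(missing)
    genes: list[str] = []
    index: dict[str, int] = {}
    for f in x.feature_ids:
        g = gene_of[f]
        if g not in index:
            index[g] = len(genes)
            genes.append(g)
    out = np.zeros((len(genes), len(x.sample_ids)))
    for i, f in enumerate(x.feature_ids):
        out[index[gene_of[f]]] += x.values[i]
    return ExpressionMatrix(genes, list(x.sample_ids), out)


def flag_pca_outliers(
    x: ExpressionMatrix,
    n_components: int = 2,
    mad_multiplier: float = 6.0,
) -> set[str]:
    """Flag samples far from the bulk in top-component PCA score space.

    Samples are log2(FPKM+1)-transformed, projected on the top principal
    components, and flagged when any component score deviates from the
    component-wise median by more than ``mad_multiplier`` times that
    component's median absolute deviation.  Deterministic given inputs.
    """
    n = len(x.sample_ids)
    if n < 3:
        raise ValidationError("PCA outlier flagging needs at least 3 samples")
    if n < n_components:
        raise ValidationError(f"{n} samples but {n_components} components requested")
    logged = np.log2(x.values + 1.0).T  # samples x features
    if np.allclose(logged, logged[0]):
        return set()
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(logged)
    med = np.median(scores, axis=0)
    dev = np.abs(scores - med)
    mad = np.median(dev, axis=0)
    # mad_multiplier=inf with mad=0 gives nan thresholds: comparison is False,
    # so an infinite multiplier never flags anything.
    with np.errstate(invalid="ignore"):
        flagged = (dev > mad_multiplier * mad).any(axis=1)
    return {x.sample_ids[i] for i in np.nonzero(flagged)[0]}
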