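"""Core dataset container, delimited-text I/O, standardization, splitting, accuracy.

A :class:`LabeledDataset` is the in-memory form of a sample-by-feature numeric
matrix with one class label per sample — the shape microarray / expression-style
classification data takes after export to CSV/TSV.  Missing entries are stored
as ``NaN``; labels are opaque strings (2–5 unordered classes is typical for this
kind of data, so no numeric coercion is ever attempted).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "StandardizationParams",
    "ConfusionCounts",
    "DatasetFormatError",
    "read_labeled_dataset",
    "write_labeled_dataset",
    "standardize",
    "destandardize",
    "stratified_split",
    "accuracy",
    "classification_accuracy",
]

#: Floor applied to a per-feature standard deviation so that constant features
#: standardize to zero instead of dividing by zero.
SIGMA_FLOOR = 1e-8


class DatasetFormatError(ValueError):
    """Raised when a delimited file violates the labelled-matrix format."""


@dataclass
class LabeledDataset:
    """N samples × D features with per-sample class labels.

    Parameters
    ----------
    matrix
        Float array of shape (N, D); ``NaN`` marks a missing entry.
    labels
        Length-N array of class identifiers (strings).
    feature_names
        Length-D unique feature names.
    sample_ids
        Length-N sample identifiers.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (samples x features)")
        self.labels = np.asarray(self.labels, dtype=object)
        n, d = self.matrix.shape
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(d)]
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError(
                f"label count {len(self.labels)} != sample count {n}"
            )
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if len(self.feature_names) != d:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != d:
            raise DatasetFormatError("duplicate feature name")

    # -- basic views -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.matrix).any())

    @property
    def observation_mask(self) -> np.ndarray:
        """Binary indicator Z with Z[i, n] = 1 iff entry (i, n) is observed."""
        return (~np.isnan(self.matrix)).astype(np.int8)

    def require_classification(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("classification requires >= 2 distinct labels")

    def take_samples(self, idx: np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            self.matrix[idx].copy(),
            self.labels[idx].copy(),
            list(self.feature_names),
            [self.sample_ids[i] for i in idx],
        )

    def take_features(self, idx) -> "LabeledDataset":
        idx = np.asarray(sorted(idx), dtype=int)
        return LabeledDataset(
            self.matrix[:, idx].copy(),
            self.labels.copy(),
            [self.feature_names[j] for j in idx],
            list(self.sample_ids),
        )

    def copy(self) -> "LabeledDataset":
        return replace(
            self,
            matrix=self.matrix.copy(),
            labels=self.labels.copy(),
            feature_names=list(self.feature_names),
            sample_ids=list(self.sample_ids),
        )


@dataclass
class StandardizationParams:
    """Per-feature affine parameters: x* = (x − mu) / sigma, sigma floored > 0."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive (floored)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.mu, self.sigma], index=["mu", "sigma"])


@dataclass
class ConfusionCounts:
    """Binary (or one-vs-rest) confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _detect_sep(path: str | os.PathLike) -> str:
    return "\t" if str(path).lower().endswith(".tsv") else ","


def read_labeled_dataset(
    path: str | os.PathLike,
    label_column: str = "label",
    missing_token: str = "NA",
) -> LabeledDataset:
    """Read a delimited labelled matrix (one row per sample, header required).

    Cells equal to ``missing_token`` become missing entries; every other cell
    must parse as a real number.  A leading ``id`` column, when present, is
    used for sample ids.
    """
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise DatasetFormatError(f"label column {label_column!r} not in header")
    if df.shape[0] == 0:
        raise DatasetFormatError("no samples")

    sample_ids: list[str]
    if "id" in df.columns and label_column != "id":
        sample_ids = df["id"].tolist()
        df = df.drop(columns=["id"])
    else:
        sample_ids = [f"s{i}" for i in range(df.shape[0])]

    labels = df[label_column]
    if (labels.astype(str).str.strip() == "").any() or (
        labels.astype(str) == missing_token
    ).any():
        bad = labels[(labels.astype(str).str.strip() == "")
                     | (labels.astype(str) == missing_token)].index[0]
        raise DatasetFormatError(f"missing label at row {bad}")
    feat = df.drop(columns=[label_column])
    feature_names = list(feat.columns)
    if len(set(feature_names)) != len(feature_names):
        raise DatasetFormatError("duplicate feature name")

    matrix = np.empty(feat.shape, dtype=float)
    for j, col in enumerate(feature_names):
        raw = feat[col].to_numpy(dtype=object)
        vals = np.full(len(raw), np.nan)
        for i, cell in enumerate(raw):
            s = str(cell).strip()
            if s == missing_token:
                continue
            try:
                vals[i] = float(s)
            except ValueError as exc:
                raise DatasetFormatError(
                    f"unparseable cell {s!r} at row {i}, column {col!r}"
                ) from exc
        matrix[:, j] = vals
    return LabeledDataset(matrix, labels.to_numpy(dtype=object),
                          feature_names, sample_ids)


def write_labeled_dataset(
    ds: LabeledDataset,
    path: str | os.PathLike,
    label_column: str = "label",
    missing_token: str = "NA",
) -> None:
    """Write a dataset back to CSV/TSV (inverse of :func:`read_labeled_dataset`)."""
    sep = _detect_sep(path)
    df = pd.DataFrame(ds.matrix, columns=ds.feature_names)
    df = df.map(lambda v: missing_token if np.isnan(v) else repr(v))
    df.insert(0, label_column, ds.labels)
    df.insert(0, "id", ds.sample_ids)
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize(ds: LabeledDataset) -> tuple[LabeledDataset, StandardizationParams]:
    """Per-feature z-scoring over observed entries only.

    Uses the population standard deviation (divide by N); a constant feature
    gets sigma floored at ``SIGMA_FLOOR`` so its standardized column is zero.
    Missing entries stay missing.  The returned params invert the transform.
    """
    X = ds.matrix
    observed = ~np.isnan(X)
    if not observed.any(axis=0).all():
        j = int(np.flatnonzero(~observed.any(axis=0))[0])
        raise ValueError(
            f"feature {ds.feature_names[j]!r} has no observed values"
        )
    mu = np.nanmean(X, axis=0)
    sigma = np.nanstd(X, axis=0, ddof=0)
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    out = ds.copy()
    out.matrix = (X - mu) / sigma
    return out, StandardizationParams(mu, sigma)


def destandardize(ds: LabeledDataset, params: StandardizationParams) -> LabeledDataset:
    """Invert :func:`standardize`: x = x* · sigma + mu."""
    out = ds.copy()
    out.matrix = ds.matrix * params.sigma + params.mu
    return out


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

def stratified_split(
    ds: LabeledDataset,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded stratified partition into train/test.

    Per-class train count = floor(fraction · class size); leftover slots (so the
    train total is round(fraction · N)) go to classes by largest fractional part
    first, ties broken by class label order.  Every class keeps at least one
    sample on each side.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    ds.require_classification()
    rng = np.random.default_rng(seed)
    labels = ds.labels
    class_order = ds.classes
    sizes = {c: int(np.sum(labels == c)) for c in class_order}
    if min(sizes.values()) < 2:
        small = min(sizes, key=lambda c: sizes[c])
        raise ValueError(f"class {small!r} has fewer than 2 samples; cannot stratify")

    base = {c: int(np.floor(train_fraction * sizes[c])) for c in class_order}
    target = int(round(train_fraction * ds.n_samples))
    # clamp so both sides of every class stay non-empty
    for c in class_order:
        base[c] = min(max(base[c], 1), sizes[c] - 1)
    leftover = target - sum(base.values())
    if leftover > 0:
        frac = sorted(
            class_order,
            key=lambda c: (-(train_fraction * sizes[c] - np.floor(train_fraction * sizes[c])), c),
        )
        for c in frac:
            if leftover == 0:
                break
            if base[c] < sizes[c] - 1:
                base[c] += 1
                leftover -= 1

    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in class_order:
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        train_idx.extend(perm[: base[c]].tolist())
        test_idx.extend(perm[base[c]:].tolist())
    train_idx.sort()
    test_idx.sort()
    return ds.take_samples(np.array(train_idx)), ds.take_samples(np.array(test_idx))


# ---------------------------------------------------------------------------
# Accuracy
# ---------------------------------------------------------------------------

def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    return (counts.tp + counts.tn) / counts.total


def classification_accuracy(y_true, y_pred) -> float:
    """Multi-class accuracy: fraction of correct predictions."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if y_true.size == 0:
        raise ValueError("no evaluated samples")
    return float(np.mean(y_true == y_pred))
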