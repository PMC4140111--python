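"""Dataset container, standardization and splitting.

Standardization maps every feature column to zero mean and unit
*population* standard deviation (the 1/n denominator), the convention the
classifier's preprocessing step prescribes.  The fitted parameters are
reusable so simulation samples can be transformed with the statistics of
the data the model saw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "StandardizationParams",
    "standardize_fit",
    "standardize_apply",
    "standardize_invert",
    "split",
    "read_csv",
    "write_csv",
]


@dataclass
class Dataset:
    """Labeled tabular data: an (n_samples, n_features) matrix plus labels.

    ``y`` holds integer class labels (1..c) or real dependent values; it may
    be ``None`` for unlabeled simulation data.
    """

    X: np.ndarray
    y: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        n, p = self.X.shape
        if n < 1:
            raise ValueError("dataset must contain at least one sample")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values (NaN)")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float).ravel()
            if self.y.shape[0] != n:
                raise ValueError(
                    f"label vector length {self.y.shape[0]} != n_samples {n}"
                )
            if np.isnan(self.y).any():
                raise ValueError("y contains missing values (NaN)")
        if not self.feature_names:
            self.feature_names = [f"f{j + 1:02d}" for j in range(p)]
        elif len(self.feature_names) != p:
            raise ValueError("feature_names length mismatch")
        if not self.sample_ids:
            self.sample_ids = [f"s{i + 1:04d}" for i in range(n)]
        elif len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def take(self, idx: np.ndarray) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class StandardizationParams:
    """Per-feature centering/scaling constants (population sd, 1/n)."""

    means: np.ndarray
    scales: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float).ravel()
        self.scales = np.asarray(self.scales, dtype=float).ravel()
        if self.means.shape != self.scales.shape:
            raise ValueError("means and scales must have equal length")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")


def standardize_fit(data: Dataset | np.ndarray) -> StandardizationParams:
    """Fit per-column mean and population standard deviation.

    Raises ``ValueError`` naming the first constant (zero-variance) feature,
    because a constant column cannot be scaled to unit variance.
    """
    X = data.X if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    names = (
        data.feature_names
        if isinstance(data, Dataset)
        else [f"f{j + 1:02d}" for j in range(X.shape[1])]
    )
    means = X.mean(axis=0)
    scales = X.std(axis=0)  # numpy default ddof=0: population sd
    bad = np.flatnonzero(scales <= 0)
    if bad.size:
        raise ValueError(f"constant feature cannot be standardized: {names[bad[0]]!r}")
    return StandardizationParams(means=means, scales=scales)


def standardize_apply(
    data: Dataset | np.ndarray, params: StandardizationParams
) -> Dataset | np.ndarray:
    """Apply x' = (x - mean) / scale column-wise; shape-checked."""
    X = data.X if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    if X.shape[1] != params.means.shape[0]:
        raise ValueError(
            f"feature count {X.shape[1]} does not match params ({params.means.shape[0]})"
        )
    Xs = (X - params.means) / params.scales
    if isinstance(data, Dataset):
        return Dataset(
            X=Xs,
            y=data.y,
            feature_names=list(data.feature_names),
            sample_ids=list(data.sample_ids),
        )
    return Xs


def standardize_invert(
    data: Dataset | np.ndarray, params: StandardizationParams
) -> Dataset | np.ndarray:
    """Undo :func:`standardize_apply` (x = x' * scale + mean)."""
    X = data.X if isinstance(data, Dataset) else np.asarray(data, dtype=float)
    if X.shape[1] != params.means.shape[0]:
        raise ValueError("feature count does not match params")
    Xo = X * params.scales + params.means
    if isinstance(data, Dataset):
        return Dataset(
            X=Xo,
            y=data.y,
            feature_names=list(data.feature_names),
            sample_ids=list(data.sample_ids),
        )
    return Xo


def split(
    data: Dataset,
    train_count: int | None = None,
    train_index: np.ndarray | None = None,
) -> tuple[Dataset, Dataset]:
    """Deterministic train/simulation split.

    Either ``train_count`` (leading block — the chronological convention:
    e.g. the first 45 of 60 yearly samples) or an explicit ``train_index``
    list.  The two parts are disjoint, ordered, and cover the input.
    """
    n = data.n_samples
    if train_index is not None:
        train_index = np.asarray(train_index, dtype=int)
        mask = np.zeros(n, dtype=bool)
        mask[train_index] = True
        idx_train = np.flatnonzero(mask)
        idx_sim = np.flatnonzero(~mask)
    else:
        if train_count is None:
            raise ValueError("provide train_count or train_index")
        idx_train = np.arange(train_count)
        idx_sim = np.arange(train_count, n)
    if idx_train.size == 0 or idx_sim.size == 0:
        raise ValueError(
            f"split must leave both parts nonempty (got {idx_train.size} train, "
            f"{idx_sim.size} simulation of {n})"
        )
    return data.take(idx_train), data.take(idx_sim)


def read_csv(path, label_column: str | None = "label") -> Dataset:
    """Load a dataset from CSV (header row required, '.' decimal, UTF-8).

    ``label_column`` names the class/degree column; pass ``None`` for
    unlabeled data.  An ``id`` column, when present, supplies sample ids.
    Any NaN in the numeric body is rejected.
    """
    df = pd.read_csv(path)
    sample_ids: list[str] = []
    if "id" in df.columns:
        sample_ids = df["id"].astype(str).tolist()
        df = df.drop(columns=["id"])
    y = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path}")
        y = df[label_column].to_numpy(dtype=float)
        df = df.drop(columns=[label_column])
    X = df.to_numpy(dtype=float)
    return Dataset(X=X, y=y, feature_names=list(df.columns), sample_ids=sample_ids)


def write_csv(data: Dataset, path, label_column: str = "label") -> None:
    df = pd.DataFrame(data.X, columns=data.feature_names)
    if data.y is not None:
        df[label_column] = data.y
    df.insert(0, "id", data.sample_ids)
    df.to_csv(path, index=False)
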