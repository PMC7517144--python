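"""Labelled expression-matrix I/O, min-max normalization and nested CV splits.

The canonical in-memory container is :class:`Dataset`: a dense ``float64``
sample-by-feature matrix ``X``, integer-encoded class labels ``y`` and the
ordered feature identifiers.  Files are plain delimited text (CSV/TSV) with a
header row and one column holding the class label — the common distribution
format of public microarray / RNA-seq benchmark matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """Labelled numeric matrix: samples in rows, features in columns.

    ``y`` holds contiguous integer codes ``0..n_classes-1``; ``class_names``
    maps the codes back to the original labels.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite values")
        if len(self.feature_ids) != self.X.shape[1]:
            raise ValueError("feature_ids length must equal n_features")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if np.any(np.bincount(self.y, minlength=len(self.class_names)) == 0):
            raise ValueError("every class must have at least one sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)


@dataclass
class CVPlan:
    """Two-layer cross-validation plan.

    ``outer_folds[i]`` is ``(train_idx, test_idx)``; ``inner_splits[i]`` is
    ``(inner_train_idx, validation_idx)``, both subsets of ``train_idx``.  One
    designated validation portion per outer fold serves every fitness
    evaluation of that fold's search.
    """

    outer_folds: list[tuple[np.ndarray, np.ndarray]]
    inner_splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int


def read_dataset(path: str | Path, label_column: str | int = -1) -> Dataset:
    """Read a delimited text matrix (header row) into a :class:`Dataset`.

    ``label_column`` selects the class-label column by name or integer
    position (default: last column).  Delimiter is sniffed between comma and
    tab.  Any non-numeric feature cell is an error naming its row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if "\t" in path.open().readline() else ","
    df = pd.read_csv(path, sep=sep)
    if isinstance(label_column, int):
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in {path.name}")
        label_name = label_column
    labels = df[label_name].astype(str)
    feats = df.drop(columns=[label_name])

    numeric = feats.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric feature value {feats.iat[r, c]!r} at row {r}, column {feats.columns[c]!r}"
        )
    class_names = sorted(labels.unique())
    code = {name: i for i, name in enumerate(class_names)}
    y = labels.map(code).to_numpy()
    return Dataset(
        X=numeric.to_numpy(dtype=np.float64),
        y=y,
        feature_ids=[str(c) for c in feats.columns],
        class_names=list(class_names),
    )


def write_dataset(ds: Dataset, path: str | Path, label_column: str = "class") -> None:
    """Write a dataset in the delimited format :func:`read_dataset` accepts."""
    df = pd.DataFrame(ds.X, columns=ds.feature_ids)
    df[label_column] = [ds.class_names[c] for c in ds.y]
    df.to_csv(path, index=False)


@dataclass
class MinMaxScaler:
    """Per-feature affine map to [0, 1] fitted on a designated sample subset.

    Constant features map to 0 by convention.  Applying to held-out samples
    clamps to [0, 1] so cut-point semantics and distances stay bounded.
    """

    mins: np.ndarray
    ranges: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            out = (X - self.mins) / np.where(self.ranges == 0, 1.0, self.ranges)
        out[:, self.ranges == 0] = 0.0
        return np.clip(out, 0.0, 1.0)


def minmax_normalize(
    ds: Dataset, fit_idx: np.ndarray | None = None
) -> tuple[Dataset, MinMaxScaler]:
    """Min-max normalize every feature using statistics from ``fit_idx`` only.

    Returns the fully transformed dataset (held-out samples clamped to [0, 1])
    together with the fitted scaler for reuse on new samples.
    """
    if fit_idx is None:
        fit_idx = np.arange(ds.n_samples)
    fit_idx = np.asarray(fit_idx)
    if fit_idx.size == 0:
        raise ValueError("fit_idx must be non-empty")
    sub = ds.X[fit_idx]
    mins = sub.min(axis=0)
    ranges = sub.max(axis=0) - mins
    scaler = MinMaxScaler(mins=mins, ranges=ranges)
    return (
        Dataset(scaler.transform(ds.X), ds.y, list(ds.feature_ids), list(ds.class_names)),
        scaler,
    )


def stratified_folds(
    y: np.ndarray, n_splits: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified K folds as (train, test) index pairs.

    Uses ``StratifiedKFold`` when every class can fill the folds.  When the
    smallest class has fewer samples than ``n_splits``, falls back (with a
    logged warning) to non-strict stratification: each class's shuffled
    samples are dealt round-robin to the currently smallest folds, so class
    proportions stay as even as the counts permit and tiny classes simply
    miss some folds.
    """
    y = np.asarray(y)
    smallest = np.bincount(y).min()
    if smallest >= n_splits:
        kf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return [(tr.copy(), te.copy()) for tr, te in kf.split(np.zeros(y.size), y)]
    logger.warning(
        "smallest class has %d samples < %d folds; falling back to non-strict stratification",
        smallest,
        n_splits,
    )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_splits)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        order = np.argsort([len(f) for f in folds], kind="stable")
        for j, s in enumerate(idx):
            folds[order[j % n_splits]].append(int(s))
    out = []
    all_idx = np.arange(y.size)
    for f in folds:
        test = np.sort(np.array(f, dtype=np.intp))
        out.append((np.setdiff1d(all_idx, test), test))
    return out


def make_cv_plan(ds: Dataset, outer_k: int = 10, inner_k: int = 10, seed: int = 0) -> CVPlan:
    """Build the two-layer stratified CV plan.

    The outer folds partition all samples; within each outer training set one
    stratified inner split designates the validation portion used by fitness
    evaluation.  Deterministic for a fixed seed.
    """
    if outer_k < 2 or inner_k < 2:
        raise ValueError("outer_k and inner_k must be >= 2")
    outer_folds = stratified_folds(ds.y, outer_k, seed)
    inner_splits = []
    for i, (train, _test) in enumerate(outer_folds):
        inner_train_rel, val_rel = stratified_folds(ds.y[train], inner_k, seed + 1 + i)[0]
        inner_splits.append((train[inner_train_rel], train[val_rel]))
    return CVPlan(outer_folds=outer_folds, inner_splits=inner_splits, seed=seed)
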