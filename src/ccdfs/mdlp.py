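"""Recursive entropy-based discretization under the MDL principle.

For each feature, candidate thresholds are midpoints between adjacent distinct
values that form a class boundary.  The threshold with maximal information
gain is accepted when the gain exceeds the MDL cost

    Gain(T) > log2(|S|-1)/|S| + delta(T)/|S|,
    delta(T) = log2(3^k - 2) - [k*E(S) - k1*E(S1) - k2*E(S2)],

with k, k1, k2 the number of classes present in the partition and its two
halves, and E the Shannon entropy in bits.  Accepted cuts split the partition
(S1: value <= T, S2: value > T) and both halves are discretized recursively.
Features that receive at least one cut are "discrete" (searched via cut-point
indices); the rest are "continuous" (searched via selection bits).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import Dataset


def entropy(labels) -> float:
    """Shannon entropy, in bits, of a class-label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty multiset is undefined")
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts.astype(np.float64))


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _boundary_splits(values: np.ndarray, labels: np.ndarray):
    """Candidate split positions on a sorted partition.

    Returns ``(split_idx, thresholds)`` where ``split_idx[j]`` samples go left
    of ``thresholds[j]``.  A gap between adjacent distinct values is a boundary
    unless both value-blocks are pure in the same single class.
    """
    n = values.size
    block_ids = np.empty(n, dtype=np.intp)
    block_ids[0] = 0
    np.cumsum(values[1:] != values[:-1], out=block_ids[1:])
    n_blocks = block_ids[-1] + 1
    if n_blocks < 2:
        return np.empty(0, dtype=np.intp), np.empty(0)

    k = int(labels.max()) + 1
    block_counts = np.zeros((n_blocks, k), dtype=np.int64)
    np.add.at(block_counts, (block_ids, labels), 1)
    block_sizes = block_counts.sum(axis=1)
    pure = block_counts.max(axis=1) == block_sizes
    pure_class = block_counts.argmax(axis=1)
    # gap b | b+1 is skipped only when both blocks are pure with the same class
    skip = pure[:-1] & pure[1:] & (pure_class[:-1] == pure_class[1:])
    gaps = np.flatnonzero(~skip)
    block_ends = np.cumsum(block_sizes)
    split_idx = block_ends[gaps]
    thresholds = (values[split_idx - 1] + values[split_idx]) / 2.0
    return split_idx, thresholds


def candidate_cut_points(values, labels) -> np.ndarray:
    """Boundary-point thresholds for one feature: midpoints between adjacent
    distinct sorted values whose value-blocks contain differing class labels."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(values)):
        raise ValueError("feature values must be finite")
    _, y = np.unique(labels, return_inverse=True)
    order = np.argsort(values, kind="stable")
    _, thresholds = _boundary_splits(values[order], y[order])
    return np.unique(thresholds)


def mdlp_gain(T: float, values, labels) -> float:
    """Information gain of splitting the samples at threshold ``T`` (<= goes left)."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    if not values.min() <= T < values.max():
        raise ValueError(f"threshold {T} lies outside the value range")
    left = values <= T
    return (
        entropy(labels)
        - left.mean() * entropy(labels[left])
        - (1 - left.mean()) * entropy(labels[~left])
    )


def mdlp_accepts(T: float, values, labels) -> bool:
    """MDL acceptance test for threshold ``T``: does the information gain pay
    for the extra partition description length?"""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    left = values <= T
    e_s, e_1, e_2 = entropy(labels), entropy(labels[left]), entropy(labels[~left])
    k = np.unique(labels).size
    k1 = np.unique(labels[left]).size
    k2 = np.unique(labels[~left]).size
    gain = e_s - left.mean() * e_1 - (1 - left.mean()) * e_2
    delta = np.log2(3.0**k - 2.0) - (k * e_s - k1 * e_1 - k2 * e_2)
    return gain > (np.log2(n - 1) + delta) / n


def _recurse(values: np.ndarray, labels: np.ndarray, k_total: int, out: list[float]) -> None:
    """Accept the max-gain boundary cut if it passes MDL, then split and recurse.

    ``values`` sorted ascending; ``labels`` are integer codes.  Ties on gain
    break toward the smallest threshold (stable argmax over sorted candidates).
    """
    n = values.size
    if n < 2:
        return
    split_idx, thresholds = _boundary_splits(values, labels)
    if split_idx.size == 0:
        return

    counts = np.zeros((n + 1, k_total), dtype=np.int64)
    np.add.at(counts[1:], (np.arange(n), labels), 1)
    np.cumsum(counts, axis=0, out=counts)
    left_counts = counts[split_idx].astype(np.float64)
    right_counts = (counts[n] - counts[split_idx]).astype(np.float64)

    def _ent(c: np.ndarray) -> np.ndarray:
        tot = c.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = c / tot
            term = np.where(c > 0, p * np.log2(p), 0.0)
        return -term.sum(axis=1)

    e_s = _entropy_from_counts(counts[n].astype(np.float64))
    e_1, e_2 = _ent(left_counts), _ent(right_counts)
    frac_left = split_idx / n
    gains = e_s - frac_left * e_1 - (1 - frac_left) * e_2

    best = int(np.argmax(gains))
    k = int(np.count_nonzero(counts[n]))
    k1 = int(np.count_nonzero(left_counts[best]))
    k2 = int(np.count_nonzero(right_counts[best]))
    delta = np.log2(3.0**k - 2.0) - (k * e_s - k1 * e_1[best] - k2 * e_2[best])
    if gains[best] <= (np.log2(n - 1) + delta) / n:
        return

    out.append(float(thresholds[best]))
    i = int(split_idx[best])
    _recurse(values[:i], labels[:i], k_total, out)
    _recurse(values[i:], labels[i:], k_total, out)


def discretize_feature(values, labels) -> np.ndarray:
    """All MDL-accepted cut thresholds for one feature, sorted ascending."""
    values = np.asarray(values, dtype=np.float64)
    _, y = np.unique(np.asarray(labels), return_inverse=True)
    order = np.argsort(values, kind="stable")
    cuts: list[float] = []
    _recurse(values[order], y[order], int(y.max()) + 1, cuts)
    return np.sort(np.asarray(cuts))


@dataclass
class CutPointTable:
    """Per-feature sorted MDL cut thresholds plus the induced feature split.

    ``cuts[f]`` is strictly increasing; ``n_cuts[f] = len(cuts[f])``.  Features
    with at least one cut are ``discrete_features``; the rest are
    ``continuous_features`` (both in original feature order).
    """

    cuts: list[np.ndarray]
    feature_ids: list[str]

    @property
    def n_cuts(self) -> np.ndarray:
        return np.array([c.size for c in self.cuts], dtype=np.intp)

    @property
    def discrete_features(self) -> np.ndarray:
        return np.flatnonzero(self.n_cuts >= 1)

    @property
    def continuous_features(self) -> np.ndarray:
        return np.flatnonzero(self.n_cuts == 0)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            fid: [float(t) for t in c] for fid, c in zip(self.feature_ids, self.cuts)
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CutPointTable":
        text = Path(source).read_text() if Path(source).exists() else str(source)
        payload = json.loads(text)
        return cls(
            cuts=[np.asarray(v, dtype=np.float64) for v in payload.values()],
            feature_ids=list(payload.keys()),
        )


def build_cut_point_table(ds: Dataset, fit_idx=None) -> CutPointTable:
    """Discretize every feature on the fitting samples and split the feature
    set into discrete (>= 1 cut) and continuous (no cut) subsets."""
    if fit_idx is None:
        fit_idx = np.arange(ds.n_samples)
    fit_idx = np.asarray(fit_idx)
    y = ds.y[fit_idx]
    if np.unique(y).size < 2:
        raise ValueError("discretization requires at least 2 classes in the fitting samples")
    _, y = np.unique(y, return_inverse=True)
    k_total = int(y.max()) + 1
    cuts: list[np.ndarray] = []
    for f in range(ds.n_features):
        v = ds.X[fit_idx, f]
        order = np.argsort(v, kind="stable")
        found: list[float] = []
        _recurse(v[order], y[order], k_total, found)
        cuts.append(np.sort(np.asarray(found)))
    return CutPointTable(cuts=cuts, feature_ids=list(ds.feature_ids))
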