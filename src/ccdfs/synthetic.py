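"""Synthetic high-dimensional labelled data with planted feature structure.

The generator emulates the shape of public gene-expression benchmarks: far
more features than samples, imbalanced classes, and a small planted set of
informative features among pure noise.  Informative features come in two
kinds, matching the two search spaces of the selector:

* *threshold-informative* — Gaussian class-conditional means separated by
  ``threshold_margin`` noise standard deviations (> 4 by default), so an
  entropy/MDL discretizer accepts at least one cut with high probability;
* *jointly-informative pairs* — a two-class signal along a 45-degree rotated
  direction with a strongly elongated orthogonal component, so each marginal
  is nearly uninformative (no MDL cut) while the pair is jointly separable.

All remaining features are class-independent noise.  Deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import Dataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults plant 10 threshold-informative and 4 jointly-informative features
    among 1000, with 100 samples in four imbalanced classes (expected
    10/20/30/40) — a down-scaled analogue of small-sample multi-class
    microarray matrices.
    """

    n_samples: int = 100
    n_features: int = 1000
    n_threshold_informative: int = 10
    n_jointly_informative: int = 4
    n_classes: int = 4
    class_proportions: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    #: class-mean separation of threshold features, in noise-sd units
    threshold_margin: float = 5.0
    seed: int = 0

    def proportions(self) -> np.ndarray:
        if self.class_proportions is None:
            # imbalanced by default: linearly increasing class weights
            w = np.arange(1, self.n_classes + 1, dtype=float)
            p = w / w.sum()
        else:
            p = np.asarray(self.class_proportions, dtype=float)
        if p.size != self.n_classes or np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("class_proportions must be positive and sum to 1")
        return p

    def validate(self) -> None:
        if self.n_threshold_informative + self.n_jointly_informative > self.n_features:
            raise ValueError("more informative features than features")
        if self.n_jointly_informative % 2 != 0:
            raise ValueError("jointly-informative features come in pairs; need an even count")
        if self.threshold_margin <= 4.0:
            raise ValueError("threshold_margin must exceed 4 noise sd for reliable cuts")
        p = self.proportions()
        if np.any(self.n_samples * p < 1):
            raise ValueError("a class has expected sample count < 1; spec infeasible")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    threshold_idx: np.ndarray
    jointly_idx: np.ndarray
    planted_thresholds: dict[str, list[float]]

    @property
    def informative_idx(self) -> np.ndarray:
        return np.sort(np.concatenate([self.threshold_idx, self.jointly_idx]))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold_informative": [int(i) for i in self.threshold_idx],
            "jointly_informative": [int(i) for i in self.jointly_idx],
            "planted_thresholds": self.planted_thresholds,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def generate(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Draw one dataset plus its ground truth; identical output per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = spec.proportions()
    y = rng.choice(spec.n_classes, size=spec.n_samples, p=p)
    if np.unique(y).size < spec.n_classes:
        raise ValueError("a class drew zero samples; increase n_samples or its proportion")

    n, m = spec.n_samples, spec.n_features
    sd = spec.noise_sd
    X = rng.normal(0.0, sd, size=(n, m))

    # random, non-overlapping column positions for the planted features
    planted = rng.choice(m, size=spec.n_threshold_informative + spec.n_jointly_informative, replace=False)
    thr_cols = np.sort(planted[: spec.n_threshold_informative])
    joint_cols = np.sort(planted[spec.n_threshold_informative :])

    # threshold-informative: class-conditional means spaced margin*sd apart
    class_means = np.arange(spec.n_classes) * spec.threshold_margin * sd
    planted_thresholds: dict[str, list[float]] = {}
    for f in thr_cols:
        X[:, f] = class_means[y] + rng.normal(0.0, sd, size=n)
        mids = (class_means[:-1] + class_means[1:]) / 2.0
        planted_thresholds[str(int(f))] = [float(t) for t in mids]

    # jointly-informative pairs: class signal on the rotated (z1) axis, an
    # elongated shared component (z2) drowning each marginal
    signal = (y - (spec.n_classes - 1) / 2.0) * 3.0 * sd
    for a, b in zip(joint_cols[0::2], joint_cols[1::2]):
        z1 = signal + rng.normal(0.0, 0.5 * sd, size=n)
        z2 = rng.normal(0.0, 8.0 * sd, size=n)
        X[:, a] = (z2 + z1) / np.sqrt(2.0)
        X[:, b] = (z2 - z1) / np.sqrt(2.0)

    ds = Dataset(
        X=X,
        y=y,
        feature_ids=[f"f{j:05d}" for j in range(m)],
        class_names=[f"C{c}" for c in range(spec.n_classes)],
    )
    truth = GroundTruth(
        threshold_idx=thr_cols,
        jointly_idx=joint_cols,
        planted_thresholds=planted_thresholds,
    )
    return ds, truth
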