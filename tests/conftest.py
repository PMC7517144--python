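"""Shared fixtures and the independent brute-force discretization oracle.

The oracle re-derives the recursive MDL cut set with plain Python arithmetic
(Counter-based entropies, exhaustive candidate evaluation at every recursion
level) and shares no code with the package implementation.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

from ccdfs import Dataset, RunConfig, SyntheticSpec, generate


# -- independent MDL oracle ---------------------------------------------------


def _oracle_entropy(labels) -> float:
    n = len(labels)
    return -sum((c / n) * math.log2(c / n) for c in Counter(labels).values())


def _oracle_candidates(pairs):
    """Boundary midpoints on (value, label) pairs sorted by value.

    A gap between adjacent distinct values is a candidate unless the two
    value-groups each contain exactly one and the same class.
    """
    values = sorted({v for v, _ in pairs})
    groups = {v: {lab for vv, lab in pairs if vv == v} for v in values}
    cands = []
    for lo, hi in zip(values, values[1:]):
        g1, g2 = groups[lo], groups[hi]
        if len(g1) == 1 and g1 == g2:
            continue
        cands.append((lo + hi) / 2.0)
    return cands


def oracle_mdlp_cuts(values, labels) -> list[float]:
    """All recursively accepted MDL cuts for one feature, sorted ascending."""

    def recurse(pairs):
        n = len(pairs)
        if n < 2 or len({lab for _, lab in pairs}) < 2:
            return []
        best_t, best_gain, best_split = None, -1.0, None
        e_s = _oracle_entropy([lab for _, lab in pairs])
        for t in sorted(_oracle_candidates(pairs)):
            s1 = [p for p in pairs if p[0] <= t]
            s2 = [p for p in pairs if p[0] > t]
            gain = (
                e_s
                - len(s1) / n * _oracle_entropy([lab for _, lab in s1])
                - len(s2) / n * _oracle_entropy([lab for _, lab in s2])
            )
            if gain > best_gain:  # ties keep the smallest threshold
                best_t, best_gain, best_split = t, gain, (s1, s2)
        if best_t is None:
            return []
        s1, s2 = best_split
        k = len({lab for _, lab in pairs})
        k1 = len({lab for _, lab in s1})
        k2 = len({lab for _, lab in s2})
        e1 = _oracle_entropy([lab for _, lab in s1])
        e2 = _oracle_entropy([lab for _, lab in s2])
        delta = math.log2(3.0**k - 2.0) - (k * e_s - k1 * e1 - k2 * e2)
        if best_gain <= (math.log2(n - 1) + delta) / n:
            return []
        return recurse(s1) + [best_t] + recurse(s2)

    return sorted(recurse(list(zip(values, labels))))


def random_small_instance(rng: np.random.Generator):
    """A random discretization instance: few samples, few distinct values."""
    n = int(rng.integers(2, 41))
    n_values = int(rng.integers(1, 6))
    n_classes = int(rng.integers(1, 6))
    values = rng.integers(0, n_values, size=n).astype(float)
    labels = rng.integers(0, n_classes, size=n)
    return values, labels


# -- fixtures -----------------------------------------------------------------


@pytest.fixture
def toy_dataset() -> Dataset:
    """One perfectly thresholdable feature and one alternating (cut-free) one."""
    # col 0: classes split cleanly at 2.5; col 1: classes interleave -> no cut
    X = np.array([[1.0, 1.0], [2.0, 3.0], [3.0, 2.0], [4.0, 4.0]])
    y = np.array([0, 0, 1, 1])
    return Dataset(X=X, y=y, feature_ids=["thr", "alt"], class_names=["A", "B"])


@pytest.fixture(scope="session")
def small_synthetic():
    """Down-scaled planted dataset for driver-level tests (fast)."""
    spec = SyntheticSpec(
        n_samples=60, n_features=120, n_threshold_informative=6,
        n_jointly_informative=2, n_classes=2, seed=7,
    )
    return generate(spec)


@pytest.fixture
def fast_config() -> RunConfig:
    """Tiny populations / few iterations for driver unit tests."""
    return RunConfig(pop_min=8, pop_max=8, max_iter=10, inner_k=5, outer_k=5)
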