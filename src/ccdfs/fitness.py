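"""Two-part solution encoding and the aggregate wrapper fitness.

A candidate feature subset is a pair: an integer code vector over the discrete
features (code j >= 1 selects cut-point j, 1-based; 0 deselects) and a binary
position vector over the continuous features.  Decoding binarizes each
selected discrete feature at its chosen cut (value <= cut -> bin 0, value >
cut -> bin 1) and keeps the normalized raw value of each selected continuous
feature.

Fitness (smaller is better) aggregates two terms computed on the inner
training split:

    fitness = beta * balanced_error + (1 - beta) * distance

``balanced_error`` is the mean per-class misclassification rate of a 1-NN
classifier on the designated validation portion; ``distance`` squashes the
gap between the mean farthest within-class distance (DW) and the mean nearest
between-class distance (DB) through a logistic, rewarding compact,
well-separated classes.  Both 1-NN and DW/DB use the same combined metric:
Hamming over the binarized discrete part plus Euclidean over the continuous
part.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data import Dataset
from .mdlp import CutPointTable

logger = logging.getLogger(__name__)

#: fitness assigned to a solution selecting no features at all
WORST_FITNESS = 1.0


@dataclass
class FitnessValue:
    balanced_error: float
    distance: float
    aggregate: float


@dataclass
class DiscreteIndividual:
    """GA member: one cut-point index per discrete feature (0 = unselected)."""

    codes: np.ndarray
    fitness: float = np.inf
    rank: int | None = None
    pbest_codes: np.ndarray | None = None
    pbest_fitness: float = np.inf
    distance_score: float = np.nan  # offspring-selection score, set by the GA


@dataclass
class ContinuousParticle:
    """BPSO member: selection bit + real velocity per continuous feature."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray | None = None
    pbest_fitness: float = np.inf


@dataclass
class CombinedSolution:
    codes: np.ndarray
    position: np.ndarray
    fitness: FitnessValue


@dataclass
class Representation:
    """Decoded samples: binarized discrete columns + raw continuous columns."""

    bits: np.ndarray  # (n_samples, n_selected_discrete), values in {0, 1}
    cont: np.ndarray  # (n_samples, n_selected_continuous)

    @property
    def n_selected(self) -> int:
        return self.bits.shape[1] + self.cont.shape[1]


def decode(
    codes: np.ndarray,
    position: np.ndarray,
    cpt: CutPointTable,
    ds: Dataset,
    idx: np.ndarray,
) -> Representation:
    """Build the transformed representation of samples ``idx`` for one solution."""
    disc = cpt.discrete_features
    cont = cpt.continuous_features
    codes = np.asarray(codes)
    position = np.asarray(position)
    n_cuts = cpt.n_cuts[disc]
    if np.any(codes < 0) or np.any(codes > n_cuts):
        raise ValueError("cut-point code out of range for its feature")

    sel_d = np.flatnonzero(codes >= 1)
    bits = np.empty((len(idx), sel_d.size), dtype=np.float64)
    for out_col, j in enumerate(sel_d):
        f = disc[j]
        cut = cpt.cuts[f][codes[j] - 1]  # codes are 1-based cut indices
        bits[:, out_col] = ds.X[idx, f] > cut  # lower bin (value <= cut) encodes 0

    sel_c = cont[np.flatnonzero(position == 1)]
    return Representation(bits=bits, cont=ds.X[np.ix_(idx, sel_c)])


def balanced_error(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean per-class misclassification rate (robust to class imbalance)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    classes = np.unique(truth)
    rates = [np.mean(pred[truth == c] != c) for c in classes]
    return float(np.mean(rates))


def pairwise_distances(a: Representation, b: Representation) -> np.ndarray:
    """Combined metric between two sample sets: Hamming (discrete bits) plus
    Euclidean (continuous values), summed."""
    if a.bits.shape[1] != b.bits.shape[1] or a.cont.shape[1] != b.cont.shape[1]:
        raise ValueError("representations have mismatched selected-feature layouts")
    d = np.zeros((a.bits.shape[0], b.bits.shape[0]))
    if a.bits.shape[1]:
        d += cdist(a.bits, b.bits, metric="cityblock")
    if a.cont.shape[1]:
        d += cdist(a.cont, b.cont, metric="euclidean")
    return d


def sample_distance(a: Representation, b: Representation) -> float:
    """Combined distance between two single samples."""
    return float(pairwise_distances(a, b)[0, 0])


def distance_measure_from_matrix(D: np.ndarray, labels: np.ndarray) -> float:
    """DW/DB class-separation statistic from a precomputed distance matrix."""
    labels = np.asarray(labels)
    n = D.shape[0]
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    diff = labels[:, None] != labels[None, :]

    db = np.where(diff, D, np.inf).min(axis=1).mean()
    dw_rows = np.where(same, D, -np.inf).max(axis=1)
    lonely = ~same.any(axis=1)
    if lonely.any():
        logger.debug("%d samples have no same-class partner; DW term set to 0", lonely.sum())
        dw_rows[lonely] = 0.0
    dw = dw_rows.mean()
    return float(1.0 / (1.0 + np.exp(-5.0 * (dw - db))))


def distance_measure(reps: Representation, labels: np.ndarray) -> float:
    """Logistic-squashed DW - DB statistic of a labelled sample set.

    DB: mean over samples of the distance to the nearest different-class
    sample.  DW: mean over samples of the distance to the farthest same-class
    sample.  Returns 1/(1+exp(-5(DW-DB))) in (0, 1); smaller is better.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2 or labels.size < 2:
        raise ValueError("distance measure needs >= 2 samples from >= 2 classes")
    return distance_measure_from_matrix(pairwise_distances(reps, reps), labels)


def knn1_predict(D_query_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    """1-NN labels from a query-by-train distance matrix; ties go to the
    lowest training-sample index (argmin is first-match)."""
    return y_train[np.argmin(D_query_train, axis=1)]


def evaluate(
    codes: np.ndarray,
    position: np.ndarray,
    ds: Dataset,
    cpt: CutPointTable,
    inner_train_idx: np.ndarray,
    validation_idx: np.ndarray,
    beta: float = 0.5,
) -> FitnessValue:
    """Aggregate fitness of one combined solution on one train/validation split.

    A zero-feature solution receives the worst fitness (aggregate 1) rather
    than an error so population updates stay total.
    """
    if len(validation_idx) == 0:
        raise ValueError("validation set is empty")
    if not (np.any(np.asarray(codes) >= 1) or np.any(np.asarray(position) == 1)):
        return FitnessValue(WORST_FITNESS, WORST_FITNESS, WORST_FITNESS)

    train_rep = decode(codes, position, cpt, ds, inner_train_idx)
    val_rep = decode(codes, position, cpt, ds, validation_idx)
    y_train = ds.y[inner_train_idx]
    y_val = ds.y[validation_idx]

    pred = knn1_predict(pairwise_distances(val_rep, train_rep), y_train)
    be = balanced_error(pred, y_val)
    dist = distance_measure(train_rep, y_train)
    return FitnessValue(be, dist, beta * be + (1.0 - beta) * dist)
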