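"""Decoding, balanced error, the combined metric and the aggregate fitness."""

import numpy as np
import pytest

from ccdfs import (
    Dataset,
    SyntheticSpec,
    balanced_error,
    build_cut_point_table,
    decode,
    distance_measure,
    evaluate,
    generate,
    minmax_normalize,
    sample_distance,
)
from ccdfs.fitness import Representation, pairwise_distances


@pytest.fixture
def toy_cpt(toy_dataset):
    return build_cut_point_table(toy_dataset)


def test_decode_binarizes_at_selected_cut(toy_dataset, toy_cpt):
    rep = decode(np.array([1]), np.array([0]), toy_cpt, toy_dataset,
                 np.arange(4))
    # cut at 2.5: values 1,2 fall in the lower bin (0), values 3,4 in the upper (1)
    np.testing.assert_array_equal(rep.bits[:, 0], [0, 0, 1, 1])
    assert rep.cont.shape == (4, 0)


def test_decode_empty_solution(toy_dataset, toy_cpt):
    rep = decode(np.array([0]), np.array([0]), toy_cpt, toy_dataset, np.arange(4))
    assert rep.n_selected == 0


def test_decode_rejects_out_of_range_code(toy_dataset, toy_cpt):
    with pytest.raises(ValueError):
        decode(np.array([2]), np.array([0]), toy_cpt, toy_dataset, np.arange(4))


def test_decode_keeps_continuous_values(toy_dataset, toy_cpt):
    rep = decode(np.array([0]), np.array([1]), toy_cpt, toy_dataset, np.arange(4))
    np.testing.assert_array_equal(rep.cont[:, 0], toy_dataset.X[:, 1])


@pytest.mark.parametrize(
    "pred, truth, expected",
    [
        ([0, 0, 1, 1], [0, 0, 1, 1], 0.0),
        ([1, 1, 0, 0], [0, 0, 1, 1], 1.0),
        # 2 classes of 10 samples with 1 and 2 errors: (1/2)(0.1 + 0.2)
        ([0] * 9 + [1] + [1] * 8 + [0] * 2, [0] * 10 + [1] * 10, 0.15),
    ],
)
def test_balanced_error(pred, truth, expected):
    assert balanced_error(np.array(pred), np.array(truth)) == pytest.approx(expected)


def test_sample_distance_sums_hamming_and_euclidean():
    a = Representation(bits=np.array([[0.0, 1.0]]), cont=np.array([[0.3]]))
    b = Representation(bits=np.array([[1.0, 1.0]]), cont=np.array([[0.7]]))
    assert sample_distance(a, a) == 0.0
    assert sample_distance(a, b) == pytest.approx(1.0 + 0.4)


def test_sample_distance_rejects_layout_mismatch():
    a = Representation(bits=np.zeros((1, 2)), cont=np.zeros((1, 0)))
    b = Representation(bits=np.zeros((1, 1)), cont=np.zeros((1, 0)))
    with pytest.raises(ValueError):
        sample_distance(a, b)


def test_distance_measure_half_at_equal_spread():
    # two classes at the corners of a square: DW = DB -> sigmoid(0) = 1/2
    rep = Representation(
        bits=np.zeros((4, 0)),
        cont=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]),
    )
    labels = np.array([0, 0, 1, 1])
    assert distance_measure(rep, labels) == pytest.approx(0.5)


def test_distance_measure_compact_separated_classes():
    """Mean nearest between-class distance 0.85 vs farthest within 0.1."""
    rep = Representation(bits=np.zeros((4, 0)),
                         cont=np.array([[0.0], [0.1], [0.9], [1.0]]))
    val = distance_measure(rep, np.array([0, 0, 1, 1]))
    assert val == pytest.approx(1.0 / (1.0 + np.exp(3.75)), abs=1e-9)
    # far-separated compact classes push the measure toward 0
    rep2 = Representation(bits=np.zeros((4, 0)),
                          cont=np.array([[0.0], [0.001], [99.0], [99.001]]))
    assert distance_measure(rep2, np.array([0, 0, 1, 1])) < 1e-6


def test_distance_measure_order_invariant_and_monotone():
    rng = np.random.default_rng(0)
    cont = rng.normal(size=(12, 3))
    labels = np.repeat([0, 1, 2], 4)
    rep = Representation(bits=np.zeros((12, 0)), cont=cont)
    base = distance_measure(rep, labels)

    perm = rng.permutation(12)
    rep_p = Representation(bits=np.zeros((12, 0)), cont=cont[perm])
    assert distance_measure(rep_p, labels[perm]) == pytest.approx(base)

    # shrinking every class toward its centroid lowers DW -> smaller measure
    centroids = np.stack([cont[labels == c].mean(axis=0) for c in range(3)])
    shrunk = centroids[labels] + 0.5 * (cont - centroids[labels])
    rep_s = Representation(bits=np.zeros((12, 0)), cont=shrunk)
    assert distance_measure(rep_s, labels) < base


def test_evaluate_zero_feature_solution_is_worst(toy_dataset, toy_cpt):
    fit = evaluate(np.array([0]), np.array([0]), toy_dataset, toy_cpt,
                   np.array([0, 1, 2, 3]), np.array([0, 3]))
    assert fit.aggregate == 1.0


def test_evaluate_beta_zero_equals_distance(toy_dataset, toy_cpt):
    fit = evaluate(np.array([1]), np.array([1]), toy_dataset, toy_cpt,
                   np.array([0, 1, 2, 3]), np.array([0, 3]), beta=0.0)
    assert fit.aggregate == pytest.approx(fit.distance)


def test_aggregate_is_convex_combination(toy_dataset, toy_cpt):
    for beta in [0.0, 0.3, 0.5, 0.9, 1.0]:
        fit = evaluate(np.array([1]), np.array([1]), toy_dataset, toy_cpt,
                       np.array([0, 1, 2, 3]), np.array([0, 3]), beta=beta)
        lo = min(fit.balanced_error, fit.distance)
        hi = max(fit.balanced_error, fit.distance)
        assert lo - 1e-12 <= fit.aggregate <= hi + 1e-12


def test_planted_subset_scores_well():
    """Selecting exactly the planted threshold features on clean synthetic
    data yields near-zero error and a small aggregate."""
    for seed in [0, 1, 2]:
        ds, truth = generate(SyntheticSpec(
            n_samples=80, n_features=200, n_threshold_informative=8,
            n_jointly_informative=0, n_classes=2, seed=seed))
        norm, _ = minmax_normalize(ds)
        cpt = build_cut_point_table(norm)
        disc = cpt.discrete_features
        codes = np.where(np.isin(disc, truth.threshold_idx), 1, 0)
        position = np.zeros(cpt.continuous_features.size, dtype=np.int8)
        fit = evaluate(codes, position, norm, cpt,
                       np.arange(0, 60), np.arange(60, 80))
        assert fit.aggregate < 0.2


def test_evaluate_deterministic(toy_dataset, toy_cpt):
    args = (np.array([1]), np.array([1]), toy_dataset, toy_cpt,
            np.array([0, 1, 2, 3]), np.array([1, 2]))
    assert evaluate(*args).aggregate == evaluate(*args).aggregate


def test_knn_tie_goes_to_lowest_train_index():
    from ccdfs.fitness import knn1_predict

    D = np.array([[0.5, 0.5, 0.9]])  # train samples 0 and 1 tie
    assert knn1_predict(D, np.array([7, 3, 3]))[0] == 7
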