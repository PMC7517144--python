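"""Rank schedule, Gaussian mutation, gene-donor crossover, offspring selection."""

import numpy as np
import pytest

from ccdfs import (
    Dataset,
    RankSchedule,
    build_cut_point_table,
    crossover,
    mutate,
    rank_probability,
    select_offspring,
)
from ccdfs.fitness import DiscreteIndividual


def _sched(**kw):
    defaults = dict(l_min=0.25, l_max0=0.5, size=50, t=0, it_max=100)
    defaults.update(kw)
    return RankSchedule(**defaults)


def test_best_rank_gets_floor_probability():
    for t in [0, 17, 100]:
        assert rank_probability(1, _sched(t=t)) == pytest.approx(0.25)


def test_worst_rank_at_start_gets_ceiling():
    assert rank_probability(50, _sched(t=0)) == pytest.approx(0.75)


def test_all_ranks_collapse_to_floor_at_final_iteration():
    for r in [1, 10, 25, 50]:
        assert rank_probability(r, _sched(t=100)) == pytest.approx(0.25)


def test_rank_probability_monotone_in_rank_and_iteration():
    probs = [rank_probability(r, _sched(t=10)) for r in range(1, 51)]
    assert all(a <= b for a, b in zip(probs, probs[1:]))
    over_t = [rank_probability(40, _sched(t=t)) for t in range(0, 101, 10)]
    assert all(a >= b for a, b in zip(over_t, over_t[1:]))


def _population(codes_rows, fitnesses):
    pop = []
    order = np.argsort(fitnesses, kind="stable")
    ranks = np.empty(len(fitnesses), dtype=int)
    ranks[order] = np.arange(1, len(fitnesses) + 1)
    for codes, fit, rank in zip(codes_rows, fitnesses, ranks):
        ind = DiscreteIndividual(codes=np.asarray(codes), fitness=fit)
        ind.rank = int(rank)
        pop.append(ind)
    return pop


def test_zero_probability_schedule_is_identity():
    pop = _population([[1, 2], [3, 0], [2, 2]], [0.1, 0.2, 0.3])
    sched = _sched(l_min=0.0, l_max0=0.0, size=3)
    rng = np.random.default_rng(0)
    n_cuts = np.array([3, 3])
    for i, parent in enumerate(pop):
        assert mutate(parent, i, pop, sched, n_cuts, rng).codes.tolist() == parent.codes.tolist()
        assert crossover(parent, i, pop, sched, rng).codes.tolist() == parent.codes.tolist()


def test_mutation_with_identical_mate_is_degenerate():
    """parent gene == mate gene -> sigma = 0 -> the child keeps the gene."""
    pop = _population([[2, 2]] * 4, [0.1, 0.2, 0.3, 0.4])
    sched = _sched(l_min=1.0, l_max0=0.0, size=4)  # every gene gated
    rng = np.random.default_rng(1)
    for _ in range(50):
        child = mutate(pop[0], 0, pop, sched, np.array([4, 4]), rng)
        assert child.codes.tolist() == [2, 2]


def test_mutation_gene_support_and_mean():
    """parent 0 vs mate 4 (#P = 4): Gaussian branch is N(2, 4) rounded and
    clamped (mean 2 by symmetry), copy branch keeps 0 -> overall mean ~ 1."""
    pop = _population([[0]] + [[4]] * 3, [0.5, 0.1, 0.2, 0.3])
    sched = _sched(l_min=1.0, l_max0=0.0, size=4)
    rng = np.random.default_rng(2)
    genes = np.array([
        mutate(pop[0], 0, pop, sched, np.array([4]), rng).codes[0]
        for _ in range(10_000)
    ])
    assert set(np.unique(genes)) <= {0, 1, 2, 3, 4}
    assert abs(genes.mean() - 1.0) < 0.1


def test_mutation_respects_code_bounds():
    rng = np.random.default_rng(3)
    n_cuts = np.array([1, 3, 5, 2])
    rows = [rng.integers(0, n_cuts + 1) for _ in range(6)]
    pop = _population(rows, rng.random(6))
    sched = _sched(l_min=1.0, l_max0=0.0, size=6)
    for _ in range(200):
        i = int(rng.integers(0, 6))
        child = mutate(pop[i], i, pop, sched, n_cuts, rng)
        assert np.all(child.codes >= 0) and np.all(child.codes <= n_cuts)


def test_mutation_requires_population_of_three():
    pop = _population([[1], [2]], [0.1, 0.2])
    with pytest.raises(ValueError):
        mutate(pop[0], 0, pop, _sched(size=2), np.array([4]), np.random.default_rng(0))


def test_crossover_takes_gene_from_better_ranked_pick():
    """Population of 3: the two non-parent picks are always the same pair, so
    every gated gene comes from the better-ranked of the two."""
    pop = _population([[5, 5], [7, 7], [9, 9]], [0.3, 0.1, 0.2])  # ranks 2,1,3
    sched = _sched(l_min=1.0, l_max0=0.0, size=3)
    rng = np.random.default_rng(4)
    for _ in range(50):
        child = crossover(pop[0], 0, pop, sched, rng)
        assert child.codes.tolist() == [7, 7]  # index 1 outranks index 2


def test_crossover_zero_mate_deselects_gated_genes():
    pop = _population([[3, 3, 3]] * 3, [0.1, 0.2, 0.3])
    sched = _sched(l_min=1.0, l_max0=0.0, size=3)
    child = crossover(pop[0], 0, pop, sched, np.random.default_rng(5), zero_mate=True)
    assert child.codes.tolist() == [0, 0, 0]


def test_mutation_zero_mate_pulls_codes_down():
    """Under a GA reset the mate is the zero vector: mu = parent/2, so the
    mean mutated gene drops below the parent's value."""
    pop = _population([[4]] * 4, [0.1, 0.2, 0.3, 0.4])
    sched = _sched(l_min=1.0, l_max0=0.0, size=4)
    rng = np.random.default_rng(6)
    genes = np.array([
        mutate(pop[0], 0, pop, sched, np.array([4]), rng, zero_mate=True).codes[0]
        for _ in range(4000)
    ])
    assert genes.mean() < 4.0 - 0.5


def _selection_dataset():
    X = np.array([[1.0, 9.0], [2.0, 8.0], [3.0, 1.0], [4.0, 2.0]])
    y = np.array([0, 0, 1, 1])
    return Dataset(X=X, y=y, feature_ids=["a", "b"], class_names=["A", "B"])


def test_select_offspring_keeps_best_scored_half():
    ds = _selection_dataset()
    cpt = build_cut_point_table(ds)
    assert cpt.discrete_features.size == 2
    idx = np.arange(4)
    # candidate selecting an informative feature vs candidates selecting nothing
    informative = DiscreteIndividual(codes=np.array([1, 0]))
    empty = DiscreteIndividual(codes=np.array([0, 0]))
    survivors = select_offspring([empty, informative, empty, empty], ds, cpt, idx)
    assert any(s.codes.tolist() == [1, 0] for s in survivors)


def test_select_offspring_ties_keep_input_order():
    ds = _selection_dataset()
    cpt = build_cut_point_table(ds)
    cands = [DiscreteIndividual(codes=np.array([0, 0])) for _ in range(6)]
    for i, c in enumerate(cands):
        c.fitness = float(i)  # scores all equal; fitness is not the criterion
    survivors = select_offspring(cands, ds, cpt, np.arange(4))
    assert [s.fitness for s in survivors] == [0.0, 1.0, 2.0]


def test_select_offspring_requires_even_pool():
    ds = _selection_dataset()
    cpt = build_cut_point_table(ds)
    with pytest.raises(ValueError):
        select_offspring([DiscreteIndividual(codes=np.array([0, 0]))], ds, cpt, np.arange(4))
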