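"""Rank-adaptive genetic operators for the discrete (cut-point-coded) subpopulation.

Each individual's per-gene probability of undergoing mutation or crossover is
set by its fitness rank: rank 1 (best) gets the floor probability Lmin, the
worst gets Lmin + Lmax(t), and Lmax(t) = Lmax0 * (1 - t/It) decays linearly so
the population settles in late iterations.

Mutation recombines the parent with the better of two randomly chosen other
individuals through a Gaussian draw centred on their mean with the gap as
standard deviation, rounded and clamped to the valid cut-index range.
Crossover copies genes from the better-ranked of two random picks.  During a
GA reset both operators use an all-zero mate, which pulls codes toward 0
(deselection) to escape local optima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset
from .fitness import DiscreteIndividual, decode, distance_measure_from_matrix, pairwise_distances
from .mdlp import CutPointTable

_EXP10_DENOM = float(np.exp(10.0) - 1.0)


@dataclass
class RankSchedule:
    """Rank-to-probability schedule with linearly decaying upper bound."""

    l_min: float = 0.25
    l_max0: float = 0.5
    size: int = 100  # population size S
    t: int = 0  # current iteration
    it_max: int = 100

    def l_max(self, t: int | None = None) -> float:
        t = self.t if t is None else t
        return self.l_max0 * (1.0 - t / self.it_max)


def rank_probability(r: int, sched: RankSchedule) -> float:
    """Per-gene mutation/crossover probability for an individual of rank ``r``
    (1 = best fitness): Lmin + Lmax(t) * (e^{10(r-1)/(S-1)} - 1) / (e^10 - 1)."""
    if sched.size < 2:
        raise ValueError("rank schedule needs a population of >= 2")
    if not 1 <= r <= sched.size:
        raise ValueError(f"rank {r} outside 1..{sched.size}")
    shape = (np.exp(10.0 * (r - 1) / (sched.size - 1)) - 1.0) / _EXP10_DENOM
    return float(sched.l_min + sched.l_max() * shape)


def _pick_two_others(rng: np.random.Generator, n: int, self_idx: int, size: int):
    """Two distinct uniform draws from the population excluding ``self_idx``."""
    a_red = rng.integers(0, n - 1, size=size)
    b_red = rng.integers(0, n - 2, size=size)
    b_red = b_red + (b_red >= a_red)  # distinct from the first pick
    a = a_red + (a_red >= self_idx)
    b = b_red + (b_red >= self_idx)
    return a, b


def _better_by_fitness(a, b, fitnesses: np.ndarray):
    """Index-wise better (lower fitness; ties -> lower index) of two pick arrays."""
    fa, fb = fitnesses[a], fitnesses[b]
    take_a = (fa < fb) | ((fa == fb) & (a <= b))
    return np.where(take_a, a, b)


def mutate(
    parent: DiscreteIndividual,
    parent_idx: int,
    pop: list[DiscreteIndividual],
    sched: RankSchedule,
    n_cuts: np.ndarray,
    rng: np.random.Generator,
    zero_mate: bool = False,
) -> DiscreteIndividual:
    """Gaussian-recombination mutation gated per gene by the parent's rank.

    For each gated gene: with probability 1/2 draw N(mu, sigma) with
    mu = (parent + mate)/2 and sigma = |parent - mate|, round to the nearest
    integer and clamp to [0, #cuts]; otherwise keep the parent's gene.  The
    mate is the better-fitness one of two random other individuals (or the
    zero vector under a GA reset).
    """
    if len(pop) < 3:
        raise ValueError("mutation needs a population of >= 3")
    codes = parent.codes
    child = codes.copy()
    gated = np.flatnonzero(rng.random(codes.size) < rank_probability(parent.rank, sched))
    if gated.size == 0:
        return DiscreteIndividual(codes=child)

    if zero_mate:
        mate_genes = np.zeros(gated.size, dtype=codes.dtype)
    else:
        fitnesses = np.array([ind.fitness for ind in pop])
        a, b = _pick_two_others(rng, len(pop), parent_idx, gated.size)
        mates = _better_by_fitness(a, b, fitnesses)
        all_codes = np.stack([ind.codes for ind in pop])
        mate_genes = all_codes[mates, gated]

    use_gauss = rng.random(gated.size) < 0.5
    mu = (codes[gated] + mate_genes) / 2.0
    sigma = np.abs(codes[gated] - mate_genes).astype(np.float64)
    drawn = np.rint(rng.normal(mu, sigma)).astype(codes.dtype)
    drawn = np.clip(drawn, 0, n_cuts[gated])
    child[gated] = np.where(use_gauss, drawn, codes[gated])
    return DiscreteIndividual(codes=child)


def crossover(
    parent: DiscreteIndividual,
    parent_idx: int,
    pop: list[DiscreteIndividual],
    sched: RankSchedule,
    rng: np.random.Generator,
    zero_mate: bool = False,
) -> DiscreteIndividual:
    """Uniform crossover gated per gene by the parent's rank: each gated gene
    is taken from the better-ranked of two random other individuals."""
    if len(pop) < 3:
        raise ValueError("crossover needs a population of >= 3")
    codes = parent.codes
    child = codes.copy()
    gated = np.flatnonzero(rng.random(codes.size) < rank_probability(parent.rank, sched))
    if gated.size == 0:
        return DiscreteIndividual(codes=child)

    if zero_mate:
        child[gated] = 0
        return DiscreteIndividual(codes=child)

    ranks = np.array([ind.rank for ind in pop])
    a, b = _pick_two_others(rng, len(pop), parent_idx, gated.size)
    donors = _better_by_fitness(a, b, ranks.astype(np.float64))
    all_codes = np.stack([ind.codes for ind in pop])
    child[gated] = all_codes[donors, gated]
    return DiscreteIndividual(codes=child)


def select_offspring(
    offspring: list[DiscreteIndividual],
    ds: Dataset,
    cpt: CutPointTable,
    inner_train_idx: np.ndarray,
) -> list[DiscreteIndividual]:
    """Halve the 2N offspring pool by the class-separation distance measure.

    Each candidate is scored on its discrete-only representation (no
    continuous features); the N candidates with the smallest (best) scores
    survive, ties broken by candidate order.
    """
    if len(offspring) % 2 != 0:
        raise ValueError("offspring pool must have even size 2N")
    n_keep = len(offspring) // 2
    n_cont = cpt.continuous_features.size
    empty_pos = np.zeros(n_cont, dtype=np.int8)
    y = ds.y[inner_train_idx]
    scores = np.empty(len(offspring))
    for i, cand in enumerate(offspring):
        rep = decode(cand.codes, empty_pos, cpt, ds, inner_train_idx)
        scores[i] = distance_measure_from_matrix(pairwise_distances(rep, rep), y)
        cand.distance_score = float(scores[i])
    order = np.argsort(scores, kind="stable")[:n_keep]
    return [offspring[i] for i in np.sort(order)]
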