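"""Cooperative-coevolution driver: GA over cut-point codes + binary PSO over
cut-point-free features, combined per index for fitness evaluation.

One search works on one training split: features are min-max normalized and
discretized on the training samples, the GA subpopulation evolves the
discrete (cut-point) part, the BPSO swarm evolves the continuous part, and
survivor i of the GA pairs with particle i to form the combined solution that
is evaluated.  The best combined solution ever seen (gbest) supplies the
attractors for both subpopulations: its discrete half (dbest) is preserved by
elitism, its continuous half (cbest) pulls the swarm.

Two stagnation windows run off the gbest trace: after ``reset_window``
iterations without improvement one subpopulation (chosen at random) performs
a reset perturbation — GA individuals recombine with an all-zero mate, or the
swarm's cbest attractor is zeroed for one velocity update; after
``stop_window`` iterations without improvement the search stops early.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bpso import PSOConfig, update_bests, update_position, update_velocity
from .config import RunConfig
from .data import Dataset, make_cv_plan, minmax_normalize, stratified_folds
from .fitness import (
    CombinedSolution,
    ContinuousParticle,
    DiscreteIndividual,
    FitnessValue,
    decode,
    evaluate,
    knn1_predict,
    pairwise_distances,
)
from .ga import RankSchedule, crossover, mutate, select_offspring
from .mdlp import CutPointTable, build_cut_point_table

logger = logging.getLogger(__name__)

EvaluateFn = Callable[[np.ndarray, np.ndarray], FitnessValue]


@dataclass
class CoevolutionState:
    """Paired populations plus gbest bookkeeping and stagnation counters."""

    discrete_pop: list[DiscreteIndividual]
    swarm: list[ContinuousParticle]
    gbest: CombinedSolution
    t: int = 0
    stagnation_reset: int = 0
    stagnation_stop: int = 0
    pending_reset: str | None = None  # "ga" | "pso" | None
    trace: list[dict] = field(default_factory=list)
    reset_events: list[dict] = field(default_factory=list)

    @property
    def dbest(self) -> np.ndarray:
        return self.gbest.codes

    @property
    def cbest(self) -> np.ndarray:
        return self.gbest.position


class CoevolutionSearch:
    """One CC-DFS search on a fixed train/validation split.

    ``evaluate_fn`` may be overridden (e.g. a stub in tests); by default it is
    the aggregate wrapper fitness on the split.
    """

    def __init__(
        self,
        ds: Dataset,
        cpt: CutPointTable,
        inner_train_idx: np.ndarray,
        validation_idx: np.ndarray,
        config: RunConfig,
        rng: np.random.Generator,
        evaluate_fn: EvaluateFn | None = None,
    ):
        self.ds = ds
        self.cpt = cpt
        self.inner_train_idx = np.asarray(inner_train_idx)
        self.validation_idx = np.asarray(validation_idx)
        self.config = config
        self.rng = rng
        self.disc = cpt.discrete_features
        self.cont = cpt.continuous_features
        self.n_cuts_disc = cpt.n_cuts[self.disc]
        if self.disc.size == 0:
            logger.warning("no discrete features: running the swarm alone")
        if self.cont.size == 0:
            logger.warning("no continuous features: running the GA alone")
        self.pso_cfg = PSOConfig(w=config.w, c1=config.c1, c2=config.c2, v_max=config.v_max)
        self._evaluate = evaluate_fn or (
            lambda codes, position: evaluate(
                codes, position, self.ds, self.cpt,
                self.inner_train_idx, self.validation_idx, beta=self.config.beta,
            )
        )

    # -- lifecycle -----------------------------------------------------------

    def initialize(self) -> CoevolutionState:
        """Random populations of size N = clamp(n_features/20, 100, 300),
        evaluated pairwise; gbest set to the best combined solution."""
        cfg = self.config
        n = cfg.population_size(self.ds.n_features)
        codes_mat = self.rng.integers(0, self.n_cuts_disc + 1, size=(n, self.disc.size))
        positions = self.rng.integers(0, 2, size=(n, self.cont.size)).astype(np.int8)
        velocities = self.rng.uniform(-cfg.v_max, cfg.v_max, size=(n, self.cont.size))

        pop, swarm = [], []
        best_i, best_fit = 0, None
        for i in range(n):
            fit = self._evaluate(codes_mat[i], positions[i])
            pop.append(
                DiscreteIndividual(
                    codes=codes_mat[i].copy(), fitness=fit.aggregate,
                    pbest_codes=codes_mat[i].copy(), pbest_fitness=fit.aggregate,
                )
            )
            swarm.append(
                ContinuousParticle(
                    position=positions[i].copy(), velocity=velocities[i],
                    pbest_position=positions[i].copy(), pbest_fitness=fit.aggregate,
                )
            )
            if best_fit is None or fit.aggregate < best_fit.aggregate:
                best_i, best_fit = i, fit
        gbest = CombinedSolution(
            codes=pop[best_i].codes.copy(), position=swarm[best_i].position.copy(),
            fitness=best_fit,
        )
        state = CoevolutionState(discrete_pop=pop, swarm=swarm, gbest=gbest)
        self._log_iteration(state)
        return state

    def step(self, state: CoevolutionState) -> CoevolutionState:
        """One coevolution iteration: rank, breed 2N, select N, move the
        swarm, evaluate the N paired solutions and update all bests."""
        cfg = self.config
        pop, swarm = state.discrete_pop, state.swarm
        n = len(pop)
        sched = RankSchedule(
            l_min=cfg.l_min, l_max0=cfg.l_max0, size=n, t=state.t, it_max=cfg.max_iter
        )
        ga_reset = state.pending_reset == "ga"
        pso_reset = state.pending_reset == "pso"

        # rank 1 = best current aggregate fitness
        order = np.argsort([ind.fitness for ind in pop], kind="stable")
        for r, i in enumerate(order, start=1):
            pop[i].rank = r

        if self.disc.size:
            mutants = [
                mutate(pop[i], i, pop, sched, self.n_cuts_disc, self.rng, zero_mate=ga_reset)
                for i in range(n)
            ]
            crossed = [
                crossover(pop[i], i, pop, sched, self.rng, zero_mate=ga_reset)
                for i in range(n)
            ]
            survivors = select_offspring(
                mutants + crossed, self.ds, self.cpt, self.inner_train_idx
            )
            # elitism: the gbest discrete part is never lost; it displaces the
            # worst-scored survivor
            if not any(np.array_equal(s.codes, state.dbest) for s in survivors):
                worst = int(np.argmax([s.distance_score for s in survivors]))
                survivors[worst] = DiscreteIndividual(codes=state.dbest.copy())
        else:
            survivors = [DiscreteIndividual(codes=ind.codes.copy()) for ind in pop]

        cbest_attractor = (
            np.zeros_like(state.cbest) if pso_reset else state.cbest
        )
        for particle in swarm:
            particle.velocity = update_velocity(particle, cbest_attractor, self.pso_cfg, self.rng)
            particle.position = update_position(particle, self.rng)

        improved = False
        for i in range(n):
            fit = self._evaluate(survivors[i].codes, swarm[i].position)
            survivors[i].fitness = fit.aggregate
            if fit.aggregate < survivors[i].pbest_fitness:
                survivors[i].pbest_fitness = fit.aggregate
                survivors[i].pbest_codes = survivors[i].codes.copy()
            update_bests(swarm[i], fit.aggregate)
            if fit.aggregate < state.gbest.fitness.aggregate - cfg.improvement_tol:
                state.gbest = CombinedSolution(
                    codes=survivors[i].codes.copy(),
                    position=swarm[i].position.copy(),
                    fitness=fit,
                )
                improved = True

        state.discrete_pop = survivors
        state.pending_reset = None
        state.t += 1
        if improved:
            state.stagnation_reset = 0
            state.stagnation_stop = 0
        else:
            state.stagnation_reset += 1
            state.stagnation_stop += 1
        self._log_iteration(state)
        return state

    def maybe_reset(self, state: CoevolutionState) -> CoevolutionState:
        """Arm a reset perturbation for the next iteration after
        ``reset_window`` stagnant iterations; coin-flip between GA and PSO."""
        if state.stagnation_reset >= self.config.reset_window:
            state.pending_reset = "ga" if self.rng.random() < 0.5 else "pso"
            state.reset_events.append({"t": state.t, "kind": state.pending_reset})
            state.stagnation_reset = 0
        return state

    def run(self) -> CoevolutionState:
        """Iterate until ``max_iter`` or ``stop_window`` stagnant iterations."""
        state = self.initialize()
        while state.t < self.config.max_iter and state.stagnation_stop < self.config.stop_window:
            self.step(state)
            self.maybe_reset(state)
        return state

    # -- bookkeeping ---------------------------------------------------------

    def _log_iteration(self, state: CoevolutionState) -> None:
        n_sel = int(np.sum(state.dbest >= 1) + np.sum(state.cbest == 1))
        entry = {
            "t": state.t,
            "gbest_fitness": state.gbest.fitness.aggregate,
            "gbest_balanced_error": state.gbest.fitness.balanced_error,
            "gbest_distance": state.gbest.fitness.distance,
            "subset_size": n_sel,
            "stagnation_reset": state.stagnation_reset,
            "stagnation_stop": state.stagnation_stop,
        }
        state.trace.append(entry)
        logger.info(
            "t=%d gbest=%.4f subset=%d stall(reset)=%d stall(stop)=%d",
            entry["t"], entry["gbest_fitness"], n_sel,
            entry["stagnation_reset"], entry["stagnation_stop"],
        )


@dataclass
class SelectionResult:
    """Outcome of one search: the decoded gbest subset plus a full report."""

    selected_idx: np.ndarray
    selected_features: list[str]
    codes: np.ndarray
    position: np.ndarray
    fitness: FitnessValue
    cpt: CutPointTable
    report: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.report, sort_keys=True, indent=1)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text


def decode_selection(cpt: CutPointTable, codes: np.ndarray, position: np.ndarray) -> np.ndarray:
    """Original-order feature indices selected by a combined solution."""
    disc = cpt.discrete_features[np.flatnonzero(codes >= 1)]
    cont = cpt.continuous_features[np.flatnonzero(position == 1)]
    return np.sort(np.concatenate([disc, cont]))


def select_features(
    ds: Dataset,
    config: RunConfig | None = None,
    seed: int | None = None,
    train_idx: np.ndarray | None = None,
    evaluate_fn: EvaluateFn | None = None,
) -> SelectionResult:
    """Run one full CC-DFS search on ``train_idx`` (default: all samples).

    Normalizes features and builds the cut-point table on the training
    samples, designates one stratified validation portion of the training set
    for fitness evaluation, runs the coevolution loop, and returns the decoded
    gbest subset with a JSON-serializable report.
    """
    config = config or RunConfig()
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if train_idx is None:
        train_idx = np.arange(ds.n_samples)
    train_idx = np.asarray(train_idx)

    fit_idx = np.arange(ds.n_samples) if config.normalize_globally else train_idx
    norm_ds, _scaler = minmax_normalize(ds, fit_idx)
    cpt = build_cut_point_table(norm_ds, train_idx)

    inner_train_rel, val_rel = stratified_folds(ds.y[train_idx], config.inner_k, seed)[0]
    inner_train_idx, validation_idx = train_idx[inner_train_rel], train_idx[val_rel]

    search = CoevolutionSearch(
        norm_ds, cpt, inner_train_idx, validation_idx, config, rng, evaluate_fn=evaluate_fn
    )
    state = search.run()

    selected_idx = decode_selection(cpt, state.dbest, state.cbest)
    report = {
        "schema_version": 1,
        "seed": int(seed),
        "config": config.to_dict(with_sources=True),
        "n_samples": int(ds.n_samples),
        "n_features": int(ds.n_features),
        "n_discrete_features": int(cpt.discrete_features.size),
        "n_continuous_features": int(cpt.continuous_features.size),
        "iterations": int(state.t),
        "gbest_fitness": state.gbest.fitness.aggregate,
        "gbest_balanced_error": state.gbest.fitness.balanced_error,
        "gbest_distance": state.gbest.fitness.distance,
        "selected_features": [ds.feature_ids[i] for i in selected_idx],
        "subset_size": int(selected_idx.size),
        "trace": state.trace,
        "reset_events": state.reset_events,
    }
    return SelectionResult(
        selected_idx=selected_idx,
        selected_features=[ds.feature_ids[i] for i in selected_idx],
        codes=state.dbest.copy(),
        position=state.cbest.copy(),
        fitness=state.gbest.fitness,
        cpt=cpt,
        report=report,
    )


def subset_balanced_accuracy(
    ds: Dataset,
    cpt: CutPointTable,
    codes: np.ndarray,
    position: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> float:
    """Held-out 1-NN balanced accuracy of a decoded subset (combined metric).

    ``ds`` must already be normalized consistently with ``cpt``.
    """
    from .fitness import balanced_error as _be

    train_rep = decode(codes, position, cpt, ds, train_idx)
    test_rep = decode(codes, position, cpt, ds, test_idx)
    pred = knn1_predict(pairwise_distances(test_rep, train_rep), ds.y[train_idx])
    return 1.0 - _be(pred, ds.y[test_idx])


def all_features_balanced_accuracy(
    ds: Dataset, train_idx: np.ndarray, test_idx: np.ndarray
) -> float:
    """Baseline: 1-NN (Euclidean) balanced accuracy using every feature."""
    from scipy.spatial.distance import cdist

    from .fitness import balanced_error as _be

    D = cdist(ds.X[test_idx], ds.X[train_idx], metric="euclidean")
    pred = knn1_predict(D, ds.y[train_idx])
    return 1.0 - _be(pred, ds.y[test_idx])


def cross_validate(
    ds: Dataset, config: RunConfig | None = None, seed: int = 0, n_folds: int | None = None
) -> dict:
    """Two-layer CV protocol: per outer fold, run a search on the training
    portion and score the selected subset on the held-out test portion.

    ``n_folds`` limits how many outer folds are executed (all by default).
    Returns a report with per-fold subsets, accuracies and the all-features
    baseline.
    """
    config = config or RunConfig()
    plan = make_cv_plan(ds, config.outer_k, config.inner_k, seed)
    folds = plan.outer_folds if n_folds is None else plan.outer_folds[:n_folds]
    fold_reports = []
    for i, (train_idx, test_idx) in enumerate(folds):
        result = select_features(ds, config, seed=seed + i, train_idx=train_idx)
        norm_ds, _ = minmax_normalize(
            ds, np.arange(ds.n_samples) if config.normalize_globally else train_idx
        )
        acc = subset_balanced_accuracy(
            norm_ds, result.cpt, result.codes, result.position, train_idx, test_idx
        )
        base = all_features_balanced_accuracy(norm_ds, train_idx, test_idx)
        fold_reports.append(
            {
                "fold": i,
                "subset_size": int(result.selected_idx.size),
                "selected_features": result.selected_features,
                "balanced_accuracy": acc,
                "all_features_balanced_accuracy": base,
                "iterations": result.report["iterations"],
            }
        )
    union: dict[str, int] = {}
    for fr in fold_reports:
        for f in fr["selected_features"]:
            union[f] = union.get(f, 0) + 1
    return {
        "seed": int(seed),
        "folds": fold_reports,
        "mean_balanced_accuracy": float(np.mean([f["balanced_accuracy"] for f in fold_reports])),
        "mean_all_features_balanced_accuracy": float(
            np.mean([f["all_features_balanced_accuracy"] for f in fold_reports])
        ),
        "mean_subset_size": float(np.mean([f["subset_size"] for f in fold_reports])),
        "selected_feature_union_counts": union,
    }
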