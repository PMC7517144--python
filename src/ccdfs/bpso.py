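"""Binary PSO for the continuous (cut-point-free) subpopulation.

Velocities follow the standard PSO update pulled toward the particle best and
the population-best continuous part (cbest), clipped to [-Vmax, Vmax].  The
binary position does not integrate the velocity; each bit is resampled from a
Bernoulli with probability sigmoid(velocity), so a strongly positive velocity
saturates toward selecting the feature and a strongly negative one toward
discarding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitness import ContinuousParticle


@dataclass
class PSOConfig:
    """Inertia weight, acceleration coefficients and velocity bound.

    w = 0.7298 is the constriction-consistent companion of c1 = c2 = 1.49445;
    Vmax = 6 keeps sigmoid(v) within about [0.0025, 0.9975].
    """

    w: float = 0.7298
    c1: float = 1.49445
    c2: float = 1.49445
    v_max: float = 6.0


def update_velocity(
    p: ContinuousParticle,
    cbest: np.ndarray,
    cfg: PSOConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """New velocity: w*v + c1*r1*(pbest - x) + c2*r2*(cbest - x), elementwise
    with fresh uniform draws per dimension and term, clipped to [-Vmax, Vmax]."""
    x = p.position.astype(np.float64)
    pbest = (p.pbest_position if p.pbest_position is not None else p.position).astype(np.float64)
    cbest = np.asarray(cbest, dtype=np.float64)
    if cbest.shape != x.shape or pbest.shape != x.shape:
        raise ValueError("position, pbest and cbest lengths must agree")
    r1 = rng.random(x.size)
    r2 = rng.random(x.size)
    v = cfg.w * p.velocity + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (cbest - x)
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(p: ContinuousParticle, rng: np.random.Generator) -> np.ndarray:
    """Resample each bit from Bernoulli(sigmoid(v)): 1 iff rand < 1/(1+e^-v)."""
    s = 1.0 / (1.0 + np.exp(-p.velocity))
    return (rng.random(p.velocity.size) < s).astype(np.int8)


def update_bests(p: ContinuousParticle, aggregate_fitness: float) -> None:
    """Replace the particle best iff the new aggregate is strictly smaller."""
    if aggregate_fitness < p.pbest_fitness:
        p.pbest_fitness = aggregate_fitness
        p.pbest_position = p.position.copy()
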