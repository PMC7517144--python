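"""Run configuration: defaults, validation, file/flag loading, serialization.

Every published default of the method is kept here so a serialized run report
can be re-loaded as a config and reproduce the run exactly.  Parameters the
method's description leaves open (``w``, ``v_max``, ``reset_window``, the
improvement tolerance) carry ``source: artifact`` in the serialized form so
downstream readers can tell them apart from published settings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

SCHEMA_VERSION = 1

#: provenance of each default: "published" settings vs choices made by this package
PARAM_SOURCES: dict[str, str] = {
    "pop_divisor": "published",
    "pop_min": "published",
    "pop_max": "published",
    "max_iter": "published",
    "c1": "published",
    "c2": "published",
    "beta": "published",
    "l_min": "published",
    "l_max0": "published",
    "stop_window": "published",
    "w": "artifact",
    "v_max": "artifact",
    "reset_window": "artifact",
    "improvement_tol": "artifact",
    "outer_k": "published",
    "inner_k": "published",
    "normalize_globally": "artifact",
    "seed": "artifact",
}


@dataclass(frozen=True)
class RunConfig:
    """All tunables of a CC-DFS run.

    Population size is ``clamp(n_features // pop_divisor, pop_min, pop_max)``.
    ``beta`` weighs balanced error against the class-separation distance in the
    aggregate fitness; ``l_min``/``l_max0`` bound the rank-adaptive mutation and
    crossover probabilities; ``stop_window`` and ``reset_window`` are the
    stagnation windows (iterations without gbest improvement) that trigger early
    stopping and the reset perturbation, respectively.
    """

    pop_divisor: int = 20
    pop_min: int = 100
    pop_max: int = 300
    max_iter: int = 100
    c1: float = 1.49445
    c2: float = 1.49445
    beta: float = 0.5
    l_min: float = 0.25
    l_max0: float = 0.5
    stop_window: int = 11
    reset_window: int = 3
    # inertia weight: Clerc-Kennedy constriction companion of c = 1.49445
    w: float = 0.7298
    # velocity bound; sigmoid(+-6) ~ [0.0025, 0.9975], the usual BPSO saturation
    v_max: float = 6.0
    improvement_tol: float = 0.0
    outer_k: int = 10
    inner_k: int = 10
    normalize_globally: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if not 0.0 <= self.l_min <= self.l_min + self.l_max0 <= 1.0:
            raise ValueError(
                f"need 0 <= l_min <= l_min + l_max0 <= 1, got l_min={self.l_min}, l_max0={self.l_max0}"
            )
        if self.v_max <= 0:
            raise ValueError(f"v_max must be positive, got {self.v_max}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.stop_window < 1 or self.reset_window < 1:
            raise ValueError("stagnation windows must be >= 1")
        if self.pop_min < 3 or self.pop_max < self.pop_min:
            raise ValueError("population bounds must satisfy 3 <= pop_min <= pop_max")
        if self.outer_k < 2 or self.inner_k < 2:
            raise ValueError("outer_k and inner_k must be >= 2")
        if self.improvement_tol < 0:
            raise ValueError("improvement_tol must be >= 0")

    def population_size(self, n_features: int) -> int:
        """Swarm/population size for a dataset: n_features/20, clamped to [100, 300]."""
        return int(min(self.pop_max, max(self.pop_min, n_features // self.pop_divisor)))

    def to_dict(self, with_sources: bool = False) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if with_sources:
            return {
                "schema_version": SCHEMA_VERSION,
                "parameters": d,
                "sources": dict(PARAM_SOURCES),
            }
        return d


def load_config(
    path: str | Path | None = None, overrides: Mapping[str, Any] | None = None
) -> RunConfig:
    """Build a :class:`RunConfig` with precedence flags > file > defaults.

    ``path`` may point to a YAML or JSON mapping.  Unknown keys raise
    ``ValueError``; out-of-range values raise via ``RunConfig`` validation.
    """
    values: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = (
            json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        )
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        # accept a previously serialized report-style config transparently
        if "parameters" in loaded and isinstance(loaded["parameters"], dict):
            loaded = loaded["parameters"]
        values.update(loaded)
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})

    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known - {"schema_version"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    values.pop("schema_version", None)
    return RunConfig(**values)
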