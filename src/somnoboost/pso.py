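"""Particle swarm optimisation over a mixed hyperparameter search space.

Particles live in a continuous box; integer and categorical dimensions are
decoded only when a position is evaluated (round to nearest / nearest
category index on a ``[0, n)`` axis). Velocity and position follow the
classic update

    v ← ω v + c1 r1 (p_best − p) + c2 r2 (g_best − p)
    p ← p + v

with fresh r1, r2 ~ U(0, 1) per particle per dimension, positions clamped
to the box and velocities clamped to half the dimension range. Velocities
start at zero and personal bests at the initial positions. Meta-parameter
defaults are the constriction-equivalent ω = 0.7298, c1 = c2 = 1.49618.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Dimension",
    "SearchSpace",
    "PSOConfig",
    "Particle",
    "init_swarm",
    "step",
    "decode",
    "encode",
    "optimise",
    "default_xgb_space",
    "compact_xgb_space",
]


@dataclass(frozen=True)
class Dimension:
    name: str
    kind: str  # "continuous" | "integer" | "categorical"
    low: float = 0.0
    high: float = 1.0
    categories: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "integer", "categorical"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind == "categorical":
            if not self.categories:
                raise ValueError(f"{self.name}: empty category list")
        elif not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError(f"{self.name}: need finite low < high")

    @property
    def bounds(self) -> tuple[float, float]:
        if self.kind == "categorical":
            return 0.0, float(len(self.categories))
        return float(self.low), float(self.high)


@dataclass(frozen=True)
class SearchSpace:
    dims: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dims:
            raise ValueError("empty search space")

    @property
    def lows(self) -> np.ndarray:
        return np.array([d.bounds[0] for d in self.dims])

    @property
    def highs(self) -> np.ndarray:
        return np.array([d.bounds[1] for d in self.dims])


@dataclass
class PSOConfig:
    swarm_size: int = 20
    iterations: int = 30
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm size must be at least 2")
        if min(self.inertia, self.cognitive, self.social) < 0:
            raise ValueError("ω, c1, c2 must be non-negative")


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    best_position: np.ndarray
    best_fitness: float = -np.inf


def decode(position: np.ndarray, space: SearchSpace) -> dict:
    """Continuous position → hyperparameter assignment."""
    out = {}
    for value, dim in zip(position, space.dims):
        lo, hi = dim.bounds
        if not lo <= value <= hi:
            raise ValueError(f"{dim.name}: position {value} outside [{lo}, {hi}]")
        if dim.kind == "continuous":
            out[dim.name] = float(value)
        elif dim.kind == "integer":
            out[dim.name] = int(round(value))
        else:
            idx = min(int(value), len(dim.categories) - 1)
            out[dim.name] = dim.categories[idx]
    return out


def encode(assignment: dict, space: SearchSpace) -> np.ndarray:
    """Hyperparameter assignment → continuous position (decode round trip)."""
    pos = np.empty(len(space.dims))
    for i, dim in enumerate(space.dims):
        v = assignment[dim.name]
        if dim.kind == "categorical":
            pos[i] = dim.categories.index(v) + 0.5
        else:
            pos[i] = float(v)
    return pos


def init_swarm(space: SearchSpace, config: PSOConfig) -> list[Particle]:
    """Uniform random positions, zero velocities, personal best = position."""
    rng = np.random.default_rng(config.seed)
    lows, highs = space.lows, space.highs
    swarm = []
    for _ in range(config.swarm_size):
        pos = rng.uniform(lows, highs)
        swarm.append(
            Particle(
                position=pos,
                velocity=np.zeros_like(pos),
                best_position=pos.copy(),
            )
        )
    return swarm


def step(
    particles: Sequence[Particle],
    global_best: np.ndarray,
    config: PSOConfig,
    rng: np.random.Generator,
) -> None:
    """In-place velocity/position update for the whole swarm."""
    for p in particles:
        n = p.position.size
        r1 = rng.uniform(size=n)
        r2 = rng.uniform(size=n)
        p.velocity = (
            config.inertia * p.velocity
            + config.cognitive * r1 * (p.best_position - p.position)
            + config.social * r2 * (global_best - p.position)
        )
        p.position = p.position + p.velocity


def _clamp(particles: Sequence[Particle], space: SearchSpace) -> None:
    lows, highs = space.lows, space.highs
    vmax = (highs - lows) / 2
    for p in particles:
        p.velocity = np.clip(p.velocity, -vmax, vmax)
        p.position = np.clip(p.position, lows, highs)


@dataclass
class SwarmHistory:
    """Per-iteration global best; fitness is non-decreasing by construction."""

    iterations: list[int] = field(default_factory=list)
    best_fitness: list[float] = field(default_factory=list)
    best_position: list[np.ndarray] = field(default_factory=list)

    def record(self, it: int, fitness: float, position: np.ndarray) -> None:
        self.iterations.append(it)
        self.best_fitness.append(fitness)
        self.best_position.append(position.copy())


def optimise(
    space: SearchSpace,
    config: PSOConfig,
    fitness: Callable[[np.ndarray], float],
    on_iteration: Callable[[int, float], None] | None = None,
) -> tuple[dict, SwarmHistory]:
    """Maximise ``fitness(position)``; returns best decoded assignment + history.

    A particle whose fitness evaluation raises scores −inf (the event is
    logged as a warning) and the run continues. Stopping criterion: the
    configured iteration budget.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F0]))
    swarm = init_swarm(space, config)
    history = SwarmHistory()
    g_best = swarm[0].position.copy()
    g_fit = -np.inf

    def evaluate(p: Particle) -> None:
        nonlocal g_best, g_fit
        try:
            f = float(fitness(p.position))
        except Exception as exc:  # noqa: BLE001 - fitness is user code
            warnings.warn(f"fitness evaluation failed ({exc!r}); particle scored -inf")
            f = -np.inf
        if f > p.best_fitness:
            p.best_fitness = f
            p.best_position = p.position.copy()
        if f > g_fit:
            g_fit = f
            g_best = p.position.copy()

    for p in swarm:
        evaluate(p)
    history.record(0, g_fit, g_best)
    if on_iteration:
        on_iteration(0, g_fit)

    for it in range(1, config.iterations + 1):
        step(swarm, g_best, config, rng)
        _clamp(swarm, space)
        for p in swarm:
            evaluate(p)
        history.record(it, g_fit, g_best)
        if on_iteration:
            on_iteration(it, g_fit)

    return decode(g_best, space), history


def default_xgb_space() -> SearchSpace:
    """Default gradient-boosting search space (both boosters, wide bounds)."""
    return SearchSpace(
        (
            Dimension("booster", "categorical", categories=("gbtree", "dart")),
            Dimension("learning_rate", "continuous", 0.01, 0.5),
            Dimension("max_depth", "integer", 3, 12),
            Dimension("n_estimators", "integer", 100, 800),
            Dimension("min_child_weight", "integer", 1, 10),
            Dimension("gamma", "continuous", 0.0, 5.0),
            Dimension("subsample", "continuous", 0.5, 1.0),
            Dimension("colsample_bytree", "continuous", 0.5, 1.0),
            Dimension("reg_alpha", "continuous", 0.0, 2.0),
            Dimension("reg_lambda", "continuous", 0.5, 4.0),
            Dimension("sample_type", "categorical", categories=("uniform", "weighted")),
            Dimension("normalize_type", "categorical", categories=("tree", "forest")),
            Dimension("rate_drop", "continuous", 0.0, 0.5),
            Dimension("skip_drop", "continuous", 0.0, 0.5),
        )
    )


def compact_xgb_space() -> SearchSpace:
    """Smaller desk-scale space (tree booster only, moderate ensembles)."""
    return SearchSpace(
        (
            Dimension("learning_rate", "continuous", 0.05, 0.5),
            Dimension("max_depth", "integer", 3, 8),
            Dimension("n_estimators", "integer", 50, 300),
            Dimension("min_child_weight", "integer", 1, 10),
            Dimension("gamma", "continuous", 0.0, 5.0),
            Dimension("subsample", "continuous", 0.5, 1.0),
            Dimension("colsample_bytree", "continuous", 0.5, 1.0),
            Dimension("reg_alpha", "continuous", 0.0, 2.0),
            Dimension("reg_lambda", "continuous", 0.5, 4.0),
        )
    )
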