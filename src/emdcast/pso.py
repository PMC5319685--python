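"""Particle swarm optimization of network weights and thresholds.

Each particle is a candidate flat parameter vector of the forecasting
network.  Velocities evolve as

    V <- w V + c1 r1 (P_i - X) + c2 r2 (P_g - X),    X <- X + V

with inertia w decreasing linearly from 0.9 to 0.3 over the run and
time-varying acceleration coefficients: the cognitive factor c1 falls
2.5 -> 0.5 while the social factor c2 rises 0.5 -> 2.5, shifting the swarm
from independent exploration toward consensus around the global best.
r1, r2 are fresh uniforms per particle *and* per dimension.  Velocities
are clamped to [v_min, v_max]; positions are unbounded.  The fitness is
the MSE of the decoded network on the (normalized) training pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import InvalidInputError, NumericFailureError
from .mlp import MLPParameters

__all__ = [
    "PSOConfig",
    "SwarmState",
    "particle_dimension",
    "inertia_weight",
    "learning_factors",
    "encode",
    "decode",
    "fitness",
    "init_swarm",
    "step",
    "optimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings.  Defaults: 40 particles, 200 iterations, inertia
    0.9 -> 0.3, c1 2.5 -> 0.5, c2 0.5 -> 2.5, velocity in [-1, 1], early
    stop when the best fitness reaches 1e-30."""

    population: int = 40
    iterations: int = 200
    inertia_start: float = 0.9
    inertia_end: float = 0.3
    c1_start: float = 2.5
    c1_end: float = 0.5
    c2_start: float = 0.5
    c2_end: float = 2.5
    v_max: float = 1.0
    v_min: float = -1.0
    min_fitness: float = 1e-30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise InvalidInputError("population must be >= 2")
        if self.iterations < 1:
            raise InvalidInputError("iterations must be >= 1")
        if self.inertia_start < self.inertia_end:
            raise InvalidInputError("inertia must be non-increasing over the run")
        if not self.v_max > self.v_min:
            raise InvalidInputError("v_max must exceed v_min")


@dataclass
class SwarmState:
    """Mutable swarm snapshot: positions, velocities, personal bests with
    their fitnesses, the global best, and the iteration counter."""

    positions: np.ndarray  # (population, D)
    velocities: np.ndarray  # (population, D)
    personal_bests: np.ndarray  # (population, D)
    personal_best_fitness: np.ndarray  # (population,)
    global_best: np.ndarray  # (D,)
    global_best_fitness: float
    iteration: int = 0


def particle_dimension(n_i: int, n_h: int, n_0: int) -> int:
    """Length of the flat parameter vector: D = n_h + n_0 + n_i*n_h + n_h*n_0."""
    if min(n_i, n_h, n_0) < 1:
        raise InvalidInputError("layer sizes must be >= 1")
    return n_h + n_0 + n_i * n_h + n_h * n_0


def inertia_weight(t: int, cfg: PSOConfig) -> float:
    """Linear-decreasing inertia: w(t) = w_start - (w_start - w_end) t / t_max."""
    if not 0 <= t <= cfg.iterations:
        raise InvalidInputError(f"iteration {t} outside [0, {cfg.iterations}]")
    return cfg.inertia_start - (cfg.inertia_start - cfg.inertia_end) * t / cfg.iterations


def learning_factors(t: int, cfg: PSOConfig) -> tuple[float, float]:
    """Time-varying acceleration coefficients, linear in t between their
    configured endpoints."""
    if not 0 <= t <= cfg.iterations:
        raise InvalidInputError(f"iteration {t} outside [0, {cfg.iterations}]")
    frac = t / cfg.iterations
    c1 = cfg.c1_start + (cfg.c1_end - cfg.c1_start) * frac
    c2 = cfg.c2_start + (cfg.c2_end - cfg.c2_start) * frac
    return c1, c2


def encode(params: MLPParameters) -> np.ndarray:
    """Flatten network parameters into a particle position."""
    return params.to_vector()


def decode(position: np.ndarray, n_i: int, n_h: int, n_0: int = 1) -> MLPParameters:
    """Rebuild network parameters from a particle position."""
    if n_0 != 1:
        raise InvalidInputError("only single-output networks are supported")
    return MLPParameters.from_vector(position, n_i, n_h)


def make_mse_objective(
    inputs: np.ndarray, targets: np.ndarray, n_i: int, n_h: int
) -> Objective:
    """Objective closure: particle position -> training MSE of the decoded net."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    k = n_i * n_h

    # Hot loop: slice the flat vector directly instead of building the
    # parameter dataclass for every fitness evaluation.
    def objective(position: np.ndarray) -> float:
        pos = np.asarray(position, dtype=float).ravel()
        H = np.tanh(X @ pos[:k].reshape(n_h, n_i).T - pos[k : k + n_h])
        e = H @ pos[k + n_h : k + 2 * n_h] - pos[-1] - y
        return float(np.mean(e * e))

    return objective


def fitness(position: np.ndarray, inputs: np.ndarray, targets: np.ndarray) -> float:
    """Training MSE of the network encoded in ``position``.  The network
    shape is inferred from the input width and the position length."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    n_i = X.shape[1]
    pos = np.asarray(position, dtype=float).ravel()
    n_h, rem = divmod(pos.size - 1, n_i + 2)
    if rem != 0 or n_h < 1:
        raise InvalidInputError(
            f"position length {pos.size} incompatible with {n_i} inputs"
        )
    return make_mse_objective(X, targets, n_i, n_h)(pos)


def init_swarm(objective: Objective, dimension: int, cfg: PSOConfig,
               rng: np.random.Generator) -> SwarmState:
    """Seeded start: positions uniform in [-1, 1], velocities uniform in
    one tenth of the velocity box."""
    positions = rng.uniform(-1.0, 1.0, size=(cfg.population, dimension))
    velocities = rng.uniform(0.1 * cfg.v_min, 0.1 * cfg.v_max,
                             size=(cfg.population, dimension))
    fit = np.array([objective(p) for p in positions])
    if not np.all(np.isfinite(fit)):
        raise NumericFailureError("non-finite fitness in initial swarm")
    best = int(np.argmin(fit))
    return SwarmState(
        positions=positions,
        velocities=velocities,
        personal_bests=positions.copy(),
        personal_best_fitness=fit,
        global_best=positions[best].copy(),
        global_best_fitness=float(fit[best]),
    )


def step(state: SwarmState, cfg: PSOConfig, objective: Objective,
         rng: np.random.Generator | None = None) -> SwarmState:
    """One synchronous swarm update (in place; the state is also returned)."""
    rng = rng or np.random.default_rng(cfg.seed)
    w = inertia_weight(state.iteration, cfg)
    c1, c2 = learning_factors(state.iteration, cfg)
    shape = state.positions.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    state.velocities = (
        w * state.velocities
        + c1 * r1 * (state.personal_bests - state.positions)
        + c2 * r2 * (state.global_best - state.positions)
    )
    np.clip(state.velocities, cfg.v_min, cfg.v_max, out=state.velocities)
    state.positions = state.positions + state.velocities

    fit = np.array([objective(p) for p in state.positions])
    if not np.all(np.isfinite(fit)):
        raise NumericFailureError(f"non-finite fitness at iteration {state.iteration}")
    improved = fit < state.personal_best_fitness
    state.personal_bests[improved] = state.positions[improved]
    state.personal_best_fitness[improved] = fit[improved]
    best = int(np.argmin(state.personal_best_fitness))
    if state.personal_best_fitness[best] < state.global_best_fitness:
        state.global_best = state.personal_bests[best].copy()
        state.global_best_fitness = float(state.personal_best_fitness[best])
    state.iteration += 1
    return state


def optimize(
    objective: Objective,
    dimension: int,
    cfg: PSOConfig | None = None,
    trace_path: str | None = None,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the swarm for the configured number of iterations (early stop at
    ``min_fitness``).  Returns the best position, its fitness, and the
    per-iteration best-fitness history (non-increasing).  Deterministic
    given ``cfg.seed``."""
    cfg = cfg or PSOConfig()
    if dimension < 1:
        raise InvalidInputError("dimension must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    state = init_swarm(objective, dimension, cfg, rng)
    history = []
    for _ in range(cfg.iterations):
        step(state, cfg, objective, rng)
        history.append(state.global_best_fitness)
        if state.global_best_fitness <= cfg.min_fitness:
            break
    history_arr = np.asarray(history)
    if trace_path is not None:
        with open(trace_path, "w", encoding="utf-8") as fh:
            fh.write("iteration,best_fitness\n")
            for i, f in enumerate(history_arr, start=1):
                fh.write(f"{i},{f!r}\n")
    return state.global_best.copy(), state.global_best_fitness, history_arr
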