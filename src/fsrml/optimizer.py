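"""Sooty tern optimisation (STOA) and its improved variant (ISTOA).

STOA is a swarm metaheuristic in which each candidate ("tern") performs a
migration phase -- collision avoidance via a linearly shrinking control
factor, then convergence toward the current best -- followed by a spiral
attack around the best solution.  ISTOA augments it with three strategies:

* Bernoulli chaotic-map initialisation, spreading the initial population
  more ergodically than uniform sampling;
* Cauchy mutation of the incumbent best, ``X_new = X_best + X_best * c``
  with heavy-tailed standard-Cauchy noise ``c``, to escape local optima;
* longitudinal-lateral (crisscross) crossover: arithmetic crossover between
  paired individuals (lateral/horizontal) and between two dimensions of one
  individual (longitudinal/vertical), both with greedy acceptance.

Objectives are minimised.  An objective is a vectorised callable mapping an
``(n, d)`` array of positions to ``(n,)`` fitness values; wrap scalar
functions with :func:`vectorize_objective`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Tuple

import numpy as np

__all__ = [
    "OptimizerConfig",
    "OptimizationTrace",
    "bernoulli_map_sequence",
    "chaotic_init",
    "stoa_step",
    "cauchy_perturb_best",
    "crossover_mutate",
    "optimize",
    "vectorize_objective",
]

Objective = Callable[[np.ndarray], np.ndarray]
Bounds = Tuple[np.ndarray, np.ndarray]


@dataclass
class OptimizerConfig:
    """Tunable parameters shared by STOA and ISTOA.

    ``bernoulli_lambda`` is the chaotic-map breakpoint parameter (0.4 by
    convention).  ``control_factor_cf`` is the migration constant from which
    the collision-avoidance factor decays linearly to zero.  ``spiral_u`` and
    ``spiral_v`` shape the attack spiral radius ``r = u * exp(-v * theta)``
    with the spiral angle ``theta`` drawn uniformly on ``[0, 2*pi)``.
    """

    population_size: int = 30
    max_iterations: int = 500
    bernoulli_lambda: float = 0.4
    cauchy_probability: float = 0.5
    crossover_horizontal_prob: float = 1.0
    crossover_vertical_prob: float = 0.6
    seed: int = 0
    control_factor_cf: float = 2.0
    spiral_u: float = 1.0
    spiral_v: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.bernoulli_lambda < 1.0:
            raise ValueError("bernoulli_lambda must lie strictly in (0, 1)")
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4 (crossover pairs individuals)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        for name in ("cauchy_probability", "crossover_horizontal_prob",
                     "crossover_vertical_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def with_(self, **kwargs) -> "OptimizerConfig":
        return replace(self, **kwargs)


@dataclass
class OptimizationTrace:
    """Per-iteration record of one optimisation run."""

    best_fitness_per_iteration: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    evaluations_used: int
    variant: str = "ISTOA"


def _as_bounds(bounds, dimension: int) -> Bounds:
    lower, upper = bounds
    lower = np.broadcast_to(np.asarray(lower, dtype=float), (dimension,)).copy()
    upper = np.broadcast_to(np.asarray(upper, dtype=float), (dimension,)).copy()
    if np.any(lower >= upper):
        raise ValueError("invalid bounds: every lower must be < upper")
    return lower, upper


def vectorize_objective(f: Callable[[np.ndarray], float]) -> Objective:
    """Lift a scalar objective ``f(x) -> float`` to act on ``(n, d)`` arrays."""

    def vf(X: np.ndarray) -> np.ndarray:
        return np.array([f(row) for row in np.atleast_2d(X)], dtype=float)

    return vf


# ---------------------------------------------------------------------------
# Bernoulli chaotic map
# ---------------------------------------------------------------------------

def bernoulli_map_sequence(x0: float, lam: float, length: int) -> np.ndarray:
    """Iterate the two-branch Bernoulli shift map ``length`` times.

    x_{n+1} = x_n / (1 - lam)          for 0 < x_n < 1 - lam
    x_{n+1} = (x_n - (1 - lam)) / lam  for 1 - lam < x_n < 1

    Every element of the returned sequence lies strictly in (0, 1).  The
    first element is the image of ``x0`` (the seed itself is not returned).
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lambda must lie strictly in (0, 1)")
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie strictly in (0, 1)")
    if length < 1:
        raise ValueError("length must be >= 1")
    eps = 1e-12
    out = np.empty(length)
    x = float(x0)
    split = 1.0 - lam
    for i in range(length):
        if x < split:
            x = x / split
        else:
            x = (x - split) / lam
        # keep strictly inside (0, 1); exact boundary hits would freeze the map
        if x <= 0.0 or x >= 1.0 or x == split:
            x = min(max(x, eps), 1.0 - eps)
            if x == split:
                x += eps
        out[i] = x
    return out


def chaotic_init(config: OptimizerConfig, bounds, dimension: int,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Bernoulli-chaotic initial population mapped onto the search box.

    One continuing chaotic stream of ``population_size * dimension`` values
    (seeded via ``config.seed`` unless an ``rng`` is supplied) fills the
    population row by row; component ``j`` of individual ``i`` is
    ``lower_j + chaos * (upper_j - lower_j)``.
    """
    lower, upper = _as_bounds(bounds, dimension)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lam = config.bernoulli_lambda
    x0 = rng.uniform(1e-6, 1.0 - 1e-6)
    while x0 in (1.0 - lam,):
        x0 = rng.uniform(1e-6, 1.0 - 1e-6)
    chaos = bernoulli_map_sequence(x0, lam, config.population_size * dimension)
    grid = chaos.reshape(config.population_size, dimension)
    return lower + grid * (upper - lower)


# ---------------------------------------------------------------------------
# STOA migration + attack step
# ---------------------------------------------------------------------------

def stoa_step(positions: np.ndarray, fitness: np.ndarray,
              best_position: np.ndarray, best_fitness: float,
              iteration: int, config: OptimizerConfig,
              objective: Objective, bounds,
              rng: np.random.Generator):
    """One synchronous STOA update of the whole population.

    Migration: collision avoidance ``C = S_A * P`` with ``S_A`` decaying
    linearly from Cf to 0 over the iteration budget; convergence toward the
    best ``M = C_B * (P_best - P)`` with ``C_B = 0.5 * rand``; ``D = C + M``.
    Attack: spiral ``P <- D * (x' + y' + z') * P_best`` with
    ``x' = r sin(theta)``, ``y' = r cos(theta)``, ``z' = r * theta`` and
    ``r = u * exp(-v * theta)``, ``theta ~ U[0, 2*pi)`` per component.
    Positions are clamped to bounds; the incumbent best is replaced only by
    an improving candidate (elitism).
    """
    lower, upper = _as_bounds(bounds, positions.shape[1])
    n = positions.shape[0]
    cf = config.control_factor_cf
    sa = cf - iteration * (cf / config.max_iterations)
    # cb and the spiral angle are drawn per component, as in the base
    # algorithm's element-wise update loop
    cb = 0.5 * rng.random(positions.shape)
    D = sa * positions + cb * (best_position[None, :] - positions)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=positions.shape)
    # decaying spiral radius: each turn of the attack spiral tightens; the
    # growing form e^{+v*theta} multiplies every component into the clamp
    # and stalls, so the contracting form is the one that reproduces the
    # base algorithm's published convergence behaviour
    r = config.spiral_u * np.exp(-config.spiral_v * theta)
    s = r * (np.sin(theta) + np.cos(theta) + theta)
    new_positions = np.clip(D * s * best_position[None, :], lower, upper)
    new_fitness = np.asarray(objective(new_positions), dtype=float)
    i_best = int(np.argmin(new_fitness))
    if new_fitness[i_best] < best_fitness:
        best_fitness = float(new_fitness[i_best])
        best_position = new_positions[i_best].copy()
    return new_positions, new_fitness, best_position, best_fitness


# ---------------------------------------------------------------------------
# ISTOA enhancement operators
# ---------------------------------------------------------------------------

def cauchy_perturb_best(best_position: np.ndarray, best_fitness: float,
                        objective: Objective, bounds,
                        rng: np.random.Generator):
    """Heavy-tailed perturbation of the incumbent best, greedily accepted.

    Proposes ``X_new = X_best + X_best * c`` with independent standard-Cauchy
    components ``c`` (location 0, scale 1), clamps to bounds, and keeps
    whichever of the proposal and the incumbent has the lower objective.
    """
    lower, upper = _as_bounds(bounds, best_position.shape[0])
    c = rng.standard_cauchy(best_position.shape[0])
    proposal = np.clip(best_position + best_position * c, lower, upper)
    f = float(np.asarray(objective(proposal[None, :]))[0])
    if f < best_fitness:
        return proposal, f
    return best_position, best_fitness


def crossover_mutate(positions: np.ndarray, fitness: np.ndarray,
                     config: OptimizerConfig, objective: Objective,
                     bounds, rng: np.random.Generator):
    """Crisscross crossover with greedy per-individual acceptance.

    Horizontal (lateral): shuffled pairs (i, j) produce, per dimension,
    ``r * x_i + (1 - r) * x_j + c * (x_i - x_j)`` with ``r ~ U(0,1)`` and
    ``c ~ U(-1,1)`` (and symmetrically for j).  Vertical (longitudinal):
    with probability ``crossover_vertical_prob`` an individual mixes two of
    its own dimensions, ``x[d1] <- r * x[d1] + (1 - r) * x[d2]``.  Offspring
    replace their parents only on improvement.
    """
    lower, upper = _as_bounds(bounds, positions.shape[1])
    n, d = positions.shape
    positions = positions.copy()
    fitness = fitness.copy()

    # -- horizontal / lateral ------------------------------------------------
    perm = rng.permutation(n)
    n_pairs = n // 2
    left, right = perm[:n_pairs], perm[n_pairs : 2 * n_pairs]
    do_pair = rng.random(n_pairs) < config.crossover_horizontal_prob
    if np.any(do_pair):
        li, ri = left[do_pair], right[do_pair]
        xi, xj = positions[li], positions[ri]
        m = xi.shape[0]
        r1, r2 = rng.random((m, d)), rng.random((m, d))
        c1 = rng.uniform(-1.0, 1.0, (m, d))
        c2 = rng.uniform(-1.0, 1.0, (m, d))
        off_i = np.clip(r1 * xi + (1 - r1) * xj + c1 * (xi - xj), lower, upper)
        off_j = np.clip(r2 * xj + (1 - r2) * xi + c2 * (xj - xi), lower, upper)
        both = np.vstack([off_i, off_j])
        both_fit = np.asarray(objective(both), dtype=float)
        idx = np.concatenate([li, ri])
        better = both_fit < fitness[idx]
        positions[idx[better]] = both[better]
        fitness[idx[better]] = both_fit[better]

    # -- vertical / longitudinal --------------------------------------------
    do_vert = rng.random(n) < config.crossover_vertical_prob
    if np.any(do_vert) and d >= 2:
        vi = np.flatnonzero(do_vert)
        d1 = rng.integers(0, d, size=vi.size)
        d2 = (d1 + 1 + rng.integers(0, d - 1, size=vi.size)) % d
        r = rng.random(vi.size)
        off = positions[vi].copy()
        off[np.arange(vi.size), d1] = (
            r * off[np.arange(vi.size), d1] + (1 - r) * off[np.arange(vi.size), d2]
        )
        off = np.clip(off, lower, upper)
        off_fit = np.asarray(objective(off), dtype=float)
        better = off_fit < fitness[vi]
        positions[vi[better]] = off[better]
        fitness[vi[better]] = off_fit[better]

    return positions, fitness


# ---------------------------------------------------------------------------
# full runs
# ---------------------------------------------------------------------------

def optimize(objective: Objective, bounds, dimension: int,
             config: OptimizerConfig | None = None,
             variant: str = "ISTOA") -> OptimizationTrace:
    """Run STOA or ISTOA and return the per-iteration trace.

    STOA: uniform random initialisation + migration/attack steps.
    ISTOA: chaotic initialisation, then each iteration a migration/attack
    step, Cauchy mutation of the best with probability
    ``cauchy_probability``, and crisscross crossover.  A single seeded
    generator drives the whole run, so identical (config, variant) pairs
    produce identical traces.
    """
    if config is None:
        config = OptimizerConfig()
    variant = variant.upper()
    if variant not in {"STOA", "ISTOA"}:
        raise ValueError(f"unknown variant {variant!r}; use 'STOA' or 'ISTOA'")
    lower, upper = _as_bounds(bounds, dimension)
    rng = np.random.default_rng(config.seed)

    n_evals = 0

    def counted(X: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        X = np.atleast_2d(X)
        n_evals += X.shape[0]
        return np.asarray(objective(X), dtype=float)

    if variant == "ISTOA":
        positions = chaotic_init(config, (lower, upper), dimension, rng=rng)
    else:
        positions = lower + rng.random((config.population_size, dimension)) * (
            upper - lower
        )
    fitness = counted(positions)
    i0 = int(np.argmin(fitness))
    best_position, best_fitness = positions[i0].copy(), float(fitness[i0])

    trace = np.empty(config.max_iterations)
    for t in range(config.max_iterations):
        positions, fitness, best_position, best_fitness = stoa_step(
            positions, fitness, best_position, best_fitness,
            t, config, counted, (lower, upper), rng,
        )
        if variant == "ISTOA":
            if rng.random() < config.cauchy_probability:
                best_position, best_fitness = cauchy_perturb_best(
                    best_position, best_fitness, counted, (lower, upper), rng
                )
            positions, fitness = crossover_mutate(
                positions, fitness, config, counted, (lower, upper), rng
            )
            i_b = int(np.argmin(fitness))
            if fitness[i_b] < best_fitness:
                best_fitness = float(fitness[i_b])
                best_position = positions[i_b].copy()
        trace[t] = best_fitness

    return OptimizationTrace(
        best_fitness_per_iteration=trace,
        best_position=best_position,
        best_fitness=best_fitness,
        evaluations_used=n_evals,
        variant=variant,
    )
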