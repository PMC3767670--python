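"""Population metaheuristics used by the localization stage.

Two optimizers, both fully deterministic under a fixed seed:

* :func:`de_optimize` — Differential Evolution with DE/target-to-best/1
  mutation and uniform crossover.  The donor for individual ``i`` is
  ``v_i = x_i + F (x_best - x_i) + F (x_r1 - x_r2)`` with distinct random
  ``r1, r2 != i``, followed by uniform crossover at rate ``CR`` with one
  guaranteed donor coordinate, greedy selection and best-so-far tracking.
  Defaults: CR = 0.9, F = 0.7, population 64, 200 generations.

* :func:`pso_optimize` — canonical global-best Particle Swarm Optimization
  with cognitive/social constants c1 = c2 = 2.05 and an inertia weight
  linearly decreasing from 1.0 (first iteration) to 0.1 (last).
  Defaults: 24 particles, 40 iterations.

Objectives are minimized.  An objective may be marked vectorized, in which
case it receives a ``(pop, dim)`` array and returns ``(pop,)`` values; this is
how the shape-fitting energy evaluates a whole population per generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

Objective = Callable[[np.ndarray], np.ndarray | float]


@dataclass(frozen=True)
class DEParams:
    crossover_rate: float = 0.9
    F: float = 0.7
    population: int = 64
    generations: int = 200
    seed: int = 0
    vectorized: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.F <= 0:
            raise ValueError("F must be > 0")
        if self.population < 4:
            raise ValueError("DE/target-to-best/1 needs a population of at least 4")


@dataclass(frozen=True)
class PSOParams:
    particles: int = 24
    iterations: int = 40
    c1: float = 2.05
    c2: float = 2.05
    inertia_start: float = 1.0
    inertia_end: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.particles < 2:
            raise ValueError("need at least 2 particles")
        if self.inertia_start <= self.inertia_end:
            raise ValueError("inertia must decrease over time")


def _as_bounds(bounds) -> tuple[np.ndarray, np.ndarray]:
    b = np.asarray(bounds, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2 or b.size == 0:
        raise ValueError("bounds must be a non-empty (dim, 2) array")
    lo, hi = b[:, 0], b[:, 1]
    if not (np.isfinite(lo).all() and np.isfinite(hi).all() and (hi >= lo).all()):
        raise ValueError("bounds must be finite with hi >= lo")
    return lo, hi


def _evaluate(objective: Objective, pop: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        return np.asarray(objective(pop), dtype=float)
    return np.array([float(objective(x)) for x in pop])


def inertia_schedule(iteration: int, iterations: int, start: float = 1.0, end: float = 0.1) -> float:
    """Linearly interpolated inertia weight at a given iteration."""
    if iterations <= 1:
        return start
    frac = iteration / (iterations - 1)
    return start + (end - start) * frac


def de_optimize(
    objective: Objective,
    bounds,
    params: DEParams = DEParams(),
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize ``objective`` within ``bounds``; returns ``(best_x, best_f)``.

    ``init`` optionally provides the initial population (clipped to bounds);
    otherwise it is sampled uniformly.  With ``generations=0`` the best
    initial individual is returned, which is useful for evaluating a known
    configuration under the exact energy the optimizer sees.
    """
    params.validate()
    lo, hi = _as_bounds(bounds)
    dim = len(lo)
    rng = np.random.default_rng(params.seed)
    npop = params.population

    if init is not None:
        pop = np.clip(np.asarray(init, dtype=float).reshape(-1, dim), lo, hi).copy()
        if len(pop) != npop:
            raise ValueError("init population size must match params.population")
    else:
        pop = rng.uniform(lo, hi, size=(npop, dim))
    fit = _evaluate(objective, pop, params.vectorized)
    best_idx = int(np.argmin(fit))
    best_x, best_f = pop[best_idx].copy(), float(fit[best_idx])

    for _ in range(params.generations):
        xbest = pop[int(np.argmin(fit))]
        # distinct r1 != r2 != i for every target (index-shift sampling)
        idx = np.arange(npop)
        r1 = rng.integers(0, npop - 1, size=npop)
        r1 = r1 + (r1 >= idx)
        r2 = rng.integers(0, npop - 2, size=npop)
        low = np.minimum(idx, r1)
        high = np.maximum(idx, r1)
        r2 = r2 + (r2 >= low)
        r2 = r2 + (r2 >= high)
        donors = pop + params.F * (xbest - pop) + params.F * (pop[r1] - pop[r2])
        donors = np.clip(donors, lo, hi)
        cross = rng.uniform(size=(npop, dim)) < params.crossover_rate
        forced = rng.integers(0, dim, size=npop)
        cross[np.arange(npop), forced] = True
        trials = np.where(cross, donors, pop)
        tfit = _evaluate(objective, trials, params.vectorized)
        improved = tfit <= fit
        pop[improved] = trials[improved]
        fit[improved] = tfit[improved]
        gen_best = int(np.argmin(fit))
        if fit[gen_best] < best_f:
            best_f = float(fit[gen_best])
            best_x = pop[gen_best].copy()
    return best_x, best_f


def pso_optimize(
    objective: Objective,
    bounds,
    params: PSOParams = PSOParams(),
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Minimize ``objective`` with canonical global-best PSO."""
    params.validate()
    lo, hi = _as_bounds(bounds)
    dim = len(lo)
    rng = np.random.default_rng(params.seed)
    n = params.particles

    if init is not None:
        pos = np.clip(np.asarray(init, dtype=float).reshape(-1, dim), lo, hi).copy()
        if len(pos) != n:
            raise ValueError("init swarm size must match params.particles")
    else:
        pos = rng.uniform(lo, hi, size=(n, dim))
    vel = np.zeros_like(pos)
    fit = _evaluate(objective, pos, False)
    pbest, pbest_f = pos.copy(), fit.copy()
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    for it in range(params.iterations):
        w = inertia_schedule(it, params.iterations, params.inertia_start, params.inertia_end)
        r1 = rng.uniform(size=(n, dim))
        r2 = rng.uniform(size=(n, dim))
        vel = w * vel + params.c1 * r1 * (pbest - pos) + params.c2 * r2 * (gbest - pos)
        pos = np.clip(pos + vel, lo, hi)
        fit = _evaluate(objective, pos, False)
        better = fit < pbest_f
        pbest[better] = pos[better]
        pbest_f[better] = fit[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    return gbest, gbest_f
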