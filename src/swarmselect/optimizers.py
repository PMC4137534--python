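"""Population searchers over [0,1]^m candidate vectors.

Four algorithms share one candidate encoding: a continuous position in the
unit hypercube whose components strictly greater than 0.5 switch the
corresponding gene on.

* ``pso``   — inertia-weight particle swarm (velocity clamp, box clamp).
* ``cs``    — cuckoo search: Levy-flight proposals compared against random
              nests, plus probabilistic nest abandonment; best nest survives.
* ``sfl``   — shuffled frog leaping: fitness-sorted round-robin memeplexes,
              worst-frog improvement toward the memeplex best, then the
              global best, then random replacement; periodic shuffling.
* ``sfllf`` — the same local search with the uniform step multiplier
              replaced by a Levy-flight draw (scale parameter ``lf``).

Levy steps use Mantegna's algorithm with stability index beta = lambda.
All randomness flows through a single numpy Generator, so identical
(config, seed, fitness) triples give identical results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

ALGORITHMS = ("pso", "cs", "sfl", "sfllf")

FitnessFn = Callable[[np.ndarray], float]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class OptimizerConfig:
    """Algorithm choice plus every tunable, defaulted to the reference values:
    population 50, 200 generations, w=0.9, c1=c2=2.1, alpha=1, lambda=1.5,
    10 memeplexes of 5 frogs, 20 shuffles."""

    algorithm: str = "sfllf"
    dim: int = 10
    pop_size: int = 50
    generations: int = 200
    # PSO.  With w=0.9 and c1=c2=2.1 the swarm is variance-divergent, so the
    # velocity clamp is what sets the residual search granularity; a tenth of
    # the unit range keeps late-stage refinement possible.
    w: float = 0.9
    c1: float = 2.1
    c2: float = 2.1
    vmax: float = 0.1
    # cuckoo search
    alpha: float = 1.0
    lam: float = 1.5
    pa: float = 0.25
    levy_direction: str = "best"  # "best" or "none"
    abandon_mode: str = "mix"     # "mix" (difference walk) or "uniform" re-init
    # SFL / SFLLF
    n_memeplexes: int = 10
    frogs_per_memeplex: int = 5
    shuffles: int = 20
    dmax: float = 0.5
    lf: float = 1.0

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.pop_size < 1:
            raise ValueError("pop_size must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if not 0.0 <= self.pa <= 1.0:
            raise ValueError("pa must be in [0, 1]")
        if self.levy_direction not in ("best", "none"):
            raise ValueError("levy_direction must be 'best' or 'none'")
        if self.abandon_mode not in ("mix", "uniform"):
            raise ValueError("abandon_mode must be 'mix' or 'uniform'")
        if self.algorithm in ("sfl", "sfllf"):
            if self.n_memeplexes * self.frogs_per_memeplex != self.pop_size:
                raise ValueError(
                    f"pop_size {self.pop_size} != n_memeplexes x frogs_per_memeplex "
                    f"({self.n_memeplexes} x {self.frogs_per_memeplex})"
                )
            if self.generations and self.generations % self.shuffles != 0:
                raise ValueError(
                    f"generations {self.generations} must be divisible by "
                    f"shuffles {self.shuffles}"
                )


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float]  # best-ever fitness after init and after each generation
    evaluations: int


# ---------------------------------------------------------------------------
# encoding and Levy steps

def decode(position: np.ndarray) -> np.ndarray:
    """Gene indices whose component is strictly greater than 0.5.

    A component exactly at 0.5 is excluded.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position has non-finite components")
    return np.flatnonzero(position > 0.5)


def levy_step(
    lam: float, alpha: float, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """``dim`` independent heavy-tailed draws scaled by ``alpha``.

    Mantegna's algorithm with stability index beta = lam: draw
    u ~ N(0, sigma_u^2), v ~ N(0, 1) and return alpha * u / |v|^(1/beta),
    giving a symmetric step distribution with power-law tails of index lam.
    """
    if not 1.0 < lam < 3.0:
        raise ValueError(f"lam must lie in (1, 3), got {lam}")
    if alpha < 0.0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    beta = lam
    sigma_u = (
        math.gamma(1.0 + beta)
        * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return alpha * u / np.abs(v) ** (1.0 / beta)


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


# ---------------------------------------------------------------------------
# PSO

@dataclass
class PSOState:
    positions: np.ndarray       # (n, d)
    velocities: np.ndarray      # (n, d)
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray   # (n,)
    gbest_position: np.ndarray
    gbest_fitness: float


def init_pso(
    cfg: OptimizerConfig, fitness_fn: FitnessFn, rng: np.random.Generator
) -> PSOState:
    positions = rng.random((cfg.pop_size, cfg.dim))
    fits = np.asarray([fitness_fn(p) for p in positions], dtype=float)
    g = int(np.argmax(fits))
    return PSOState(
        positions=positions,
        velocities=np.zeros_like(positions),
        pbest_positions=positions.copy(),
        pbest_fitness=fits,
        gbest_position=positions[g].copy(),
        gbest_fitness=float(fits[g]),
    )


def pso_step(
    state: PSOState,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    w: float = 0.9,
    c1: float = 2.1,
    c2: float = 2.1,
    vmax: float = 1.0,
) -> PSOState:
    """One velocity/position update with fresh per-dimension uniforms.

    V <- w*V + c1*r1*(pbest - X) + c2*r2*(gbest - X), clamped to +/-vmax;
    X <- clip(X + V, 0, 1).  Personal/global bests update on strict
    improvement only (incumbent wins ties).
    """
    n, d = state.positions.shape
    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    v = (
        w * state.velocities
        + c1 * r1 * (state.pbest_positions - state.positions)
        + c2 * r2 * (state.gbest_position[None, :] - state.positions)
    )
    np.clip(v, -vmax, vmax, out=v)
    state.velocities = v
    state.positions = _clip01(state.positions + v)

    fits = np.asarray([fitness_fn(p) for p in state.positions], dtype=float)
    improved = fits > state.pbest_fitness
    state.pbest_positions[improved] = state.positions[improved]
    state.pbest_fitness[improved] = fits[improved]
    g = int(np.argmax(state.pbest_fitness))
    if state.pbest_fitness[g] > state.gbest_fitness:
        state.gbest_fitness = float(state.pbest_fitness[g])
        state.gbest_position = state.pbest_positions[g].copy()
    return state


# ---------------------------------------------------------------------------
# cuckoo search

@dataclass
class CSState:
    nests: np.ndarray           # (n, d) one egg per nest
    fitness: np.ndarray         # (n,)
    best_position: np.ndarray
    best_fitness: float

    def refresh_best(self) -> None:
        i = int(np.argmax(self.fitness))
        if self.fitness[i] > self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.nests[i].copy()


def init_cs(
    cfg: OptimizerConfig, fitness_fn: FitnessFn, rng: np.random.Generator
) -> CSState:
    nests = rng.random((cfg.pop_size, cfg.dim))
    fits = np.asarray([fitness_fn(p) for p in nests], dtype=float)
    i = int(np.argmax(fits))
    return CSState(
        nests=nests,
        fitness=fits,
        best_position=nests[i].copy(),
        best_fitness=float(fits[i]),
    )


def cs_step(
    state: CSState,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    alpha: float = 1.0,
    lam: float = 1.5,
    pa: float = 0.25,
    levy_direction: str = "best",
    abandon_mode: str = "mix",
) -> CSState:
    """One generation: Levy proposals against random nests, then abandonment.

    Each cuckoo proposes x + alpha (x) Levy(lam) — entrywise, directed along
    (x - best) in the default mode — and dumps the egg in a uniformly chosen
    nest, replacing it on strict improvement.  Afterwards discovered non-best
    nests are rebuilt; the nest count is fixed and the best nest always
    carries over.

    ``abandon_mode="mix"`` (default) rebuilds a discovered nest by a
    difference walk toward two random nests, component-discovered with
    probability pa — the reference formulation, which keeps the rebuild
    scale tied to the population spread.  ``"uniform"`` re-seeds the whole
    nest uniformly in [0,1]^m with per-nest probability pa; it reads the
    "completely new nest in a new location" rule literally but degrades the
    search to short-lived restarts.
    """
    n, d = state.nests.shape
    for i in range(n):
        step = levy_step(lam, alpha, d, rng)
        if levy_direction == "best":
            step = step * (state.nests[i] - state.best_position)
        if not step.any():  # zero-length proposal carries no information
            continue
        cand = _clip01(state.nests[i] + step)
        f_cand = fitness_fn(cand)
        j = int(rng.integers(n))
        if f_cand > state.fitness[j]:
            state.nests[j] = cand
            state.fitness[j] = f_cand
    state.refresh_best()

    if pa > 0.0:
        current_best = int(np.argmax(state.fitness))
        if abandon_mode == "uniform":
            discover = rng.random(n) < pa
            for i in range(n):
                if i == current_best or not discover[i]:
                    continue
                state.nests[i] = rng.random(d)
                state.fitness[i] = fitness_fn(state.nests[i])
        else:
            discover = rng.random((n, d)) < pa
            r = rng.random((n, d))
            p1 = rng.permutation(n)
            p2 = rng.permutation(n)
            for i in range(n):
                if i == current_best or not discover[i].any():
                    continue
                cand = _clip01(
                    state.nests[i]
                    + discover[i] * r[i] * (state.nests[p1[i]] - state.nests[p2[i]])
                )
                state.nests[i] = cand
                state.fitness[i] = fitness_fn(cand)
        state.refresh_best()
    return state


# ---------------------------------------------------------------------------
# shuffled frog leaping (+ Levy flight variant)

def sfl_sort_partition(fitness: np.ndarray, n_memeplexes: int) -> list[np.ndarray]:
    """Round-robin memeplexes over the descending-fitness sort order.

    The frog at sorted rank i goes to memeplex i mod n_memeplexes; each
    returned array holds population indices, best rank first.
    """
    fitness = np.asarray(fitness, dtype=float)
    if fitness.shape[0] % n_memeplexes != 0:
        raise ValueError(
            f"population size {fitness.shape[0]} not divisible by "
            f"{n_memeplexes} memeplexes"
        )
    order = np.argsort(-fitness, kind="stable")
    return [order[j::n_memeplexes] for j in range(n_memeplexes)]


def _attempt_step(
    positions: np.ndarray,
    fitness: np.ndarray,
    w_local: int,
    target: np.ndarray,
    step_mult: np.ndarray,
    dmax: float,
    fitness_fn: FitnessFn,
) -> bool:
    """Move the worst frog toward ``target``; accept on strict improvement."""
    d_step = step_mult * (target - positions[w_local])
    np.clip(d_step, -dmax, dmax, out=d_step)
    cand = _clip01(positions[w_local] + d_step)
    f_cand = fitness_fn(cand)
    if f_cand > fitness[w_local]:
        positions[w_local] = cand
        fitness[w_local] = f_cand
        return True
    return False


def _worst_update(
    positions: np.ndarray,
    fitness: np.ndarray,
    xg: np.ndarray,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    dmax: float,
    step_sampler: Callable[[], np.ndarray],
) -> None:
    """Shared SFL/SFLLF fallback chain; mutates the memeplex arrays in place.

    Attempt 1 leaps the worst frog toward the memeplex best, attempt 2
    toward the global best, and attempt 3 replaces it with a fresh uniform
    random frog.  Only the worst frog moves.
    """
    b = int(np.argmax(fitness))
    w = int(np.argmin(fitness))
    dim = positions.shape[1]
    if _attempt_step(positions, fitness, w, positions[b], step_sampler(), dmax, fitness_fn):
        return
    if _attempt_step(positions, fitness, w, xg, step_sampler(), dmax, fitness_fn):
        return
    positions[w] = rng.random(dim)
    fitness[w] = fitness_fn(positions[w])


def sfl_worst_update(
    positions: np.ndarray,
    fitness: np.ndarray,
    xg: np.ndarray,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    dmax: float = 0.5,
) -> None:
    """Classic worst-frog improvement with per-dimension uniform multipliers."""
    dim = positions.shape[1]
    _worst_update(
        positions, fitness, xg, fitness_fn, rng, dmax,
        step_sampler=lambda: rng.random(dim),
    )


def sfllf_worst_update(
    positions: np.ndarray,
    fitness: np.ndarray,
    xg: np.ndarray,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    lam: float = 1.5,
    lf: float = 1.0,
    dmax: float = 0.5,
    levy_sampler: Callable[[float, float, int, np.random.Generator], np.ndarray] = levy_step,
) -> None:
    """Worst-frog improvement whose step multiplier is LF times a Levy length.

    The magnitude |Levy(lam)| replaces SFL's uniform multiplier: step lengths
    are heavy-tailed while the leap direction stays toward the better frog,
    so long jumps past it remain possible (the clamp still bounds them).
    """
    dim = positions.shape[1]
    _worst_update(
        positions, fitness, xg, fitness_fn, rng, dmax,
        step_sampler=lambda: lf * np.abs(levy_sampler(lam, 1.0, dim, rng)),
    )


@dataclass
class SFLState:
    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float

    def refresh_best(self) -> None:
        i = int(np.argmax(self.fitness))
        if self.fitness[i] > self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.positions[i].copy()


# ---------------------------------------------------------------------------
# driver

class _CountingFitness:
    def __init__(self, fn: FitnessFn) -> None:
        self.fn = fn
        self.calls = 0

    def __call__(self, position: np.ndarray) -> float:
        self.calls += 1
        return float(self.fn(position))


def run_optimizer(
    cfg: OptimizerConfig, fitness_fn: FitnessFn, seed: int
) -> OptimizationResult:
    """Run the configured algorithm and return the best-ever candidate.

    The population starts uniform in [0,1]^dim.  For SFL/SFLLF the
    generation budget is organized as ``shuffles`` shuffling rounds of
    ``generations / shuffles`` worst-frog cycles over every memeplex; the
    trace records the best-ever fitness once per cycle so all algorithms
    emit ``generations + 1`` trace points (including the initial best).
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    fn = _CountingFitness(fitness_fn)

    if cfg.algorithm == "pso":
        state = init_pso(cfg, fn, rng)
        trace = [state.gbest_fitness]
        for gen in range(cfg.generations):
            pso_step(state, fn, rng, cfg.w, cfg.c1, cfg.c2, cfg.vmax)
            trace.append(state.gbest_fitness)
            logger.debug("pso gen %d best %.4f", gen + 1, state.gbest_fitness)
        best_pos, best_fit = state.gbest_position, state.gbest_fitness

    elif cfg.algorithm == "cs":
        cstate = init_cs(cfg, fn, rng)
        trace = [cstate.best_fitness]
        for gen in range(cfg.generations):
            cs_step(cstate, fn, rng, cfg.alpha, cfg.lam, cfg.pa,
                    cfg.levy_direction, cfg.abandon_mode)
            trace.append(cstate.best_fitness)
            logger.debug("cs gen %d best %.4f", gen + 1, cstate.best_fitness)
        best_pos, best_fit = cstate.best_position, cstate.best_fitness

    else:  # sfl / sfllf
        positions = rng.random((cfg.pop_size, cfg.dim))
        fits = np.asarray([fn(p) for p in positions], dtype=float)
        i0 = int(np.argmax(fits))
        state_s = SFLState(positions, fits, positions[i0].copy(), float(fits[i0]))
        trace = [state_s.best_fitness]
        cycles = cfg.generations // cfg.shuffles if cfg.generations else 0
        for shuffle in range(cfg.shuffles if cfg.generations else 0):
            memeplexes = sfl_sort_partition(state_s.fitness, cfg.n_memeplexes)
            for _cycle in range(cycles):
                for members in memeplexes:
                    mp = state_s.positions[members]
                    mf = state_s.fitness[members]
                    if cfg.algorithm == "sfl":
                        sfl_worst_update(
                            mp, mf, state_s.best_position, fn, rng, cfg.dmax
                        )
                    else:
                        sfllf_worst_update(
                            mp, mf, state_s.best_position, fn, rng,
                            cfg.lam, cfg.lf, cfg.dmax,
                        )
                    state_s.positions[members] = mp
                    state_s.fitness[members] = mf
                    state_s.refresh_best()
                trace.append(state_s.best_fitness)
            logger.debug(
                "%s shuffle %d best %.4f", cfg.algorithm, shuffle + 1,
                state_s.best_fitness,
            )
        best_pos, best_fit = state_s.best_position, state_s.best_fitness

    return OptimizationResult(
        best_position=np.asarray(best_pos, dtype=float).copy(),
        best_fitness=float(best_fit),
        trace=trace,
        evaluations=fn.calls,
    )
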