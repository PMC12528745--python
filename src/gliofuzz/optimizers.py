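"""Bounded-box population metaheuristics: PSO, transit search, and the hybrid.

All three optimizers minimize a scalar objective over an axis-aligned box,
draw every random number from one seeded generator, clamp candidates into
the box after every move, and keep an elitist best-so-far (so the best
fitness history is non-increasing by construction).  Budget accounting is
exact: each run spends ``population`` evaluations on initialization plus
``population`` per iteration, i.e. ``pop * (1 + iterations)`` total; the
hybrid hands the transit-search population (with cached fitnesses) to PSO,
so its total is the same formula over the combined iteration count.

The transit-search explorer is a documented scheme of this package: each
candidate proposes, per iteration, one move drawn from (i) a transit phase
(jump toward the global best plus heavy-tailed Cauchy noise, for escaping
basins), (ii) a neighbor phase (per-coordinate recombination with a random
other candidate), or (iii) an exploitation phase (Gaussian perturbation of
the global best with a radius that shrinks geometrically).  Proposals are
accepted greedily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

__all__ = [
    "Candidate",
    "PSOSettings",
    "TSOSettings",
    "OptimizerConfig",
    "OptResult",
    "run_pso",
    "run_tso",
    "run_hybrid",
]

logger = logging.getLogger(__name__)

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class Candidate:
    """A position-fitness pair; lower fitness is better."""

    position: np.ndarray
    fitness: float


@dataclass(frozen=True)
class PSOSettings:
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    velocity_clamp: float = 0.5  # fraction of per-dimension box range


@dataclass(frozen=True)
class TSOSettings:
    exploration_fraction: float = 0.4  # probability of a transit move
    neighbor_fraction: float = 0.3  # probability of a recombination move
    perturbation_scale: float = 0.1  # Cauchy scale, fraction of box range
    initial_radius: float = 0.3  # exploitation radius, fraction of range
    shrink_rate: float = 0.95  # radius multiplier per iteration


@dataclass(frozen=True)
class OptimizerConfig:
    bounds: np.ndarray  # shape (D, 2): per-dimension [lo, hi]
    population: int = 20
    iterations: int = 100
    seed: int = 0
    pso: PSOSettings = field(default_factory=PSOSettings)
    tso: TSOSettings = field(default_factory=TSOSettings)
    hybrid_split: float = 0.5  # fraction of iterations given to TSO

    def __post_init__(self) -> None:
        bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(bounds[:, 0] >= bounds[:, 1]):
            raise ValueError("bounds must be a (D, 2) array with lo < hi per dimension")
        object.__setattr__(self, "bounds", bounds)
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 <= self.hybrid_split <= 1.0):
            raise ValueError("hybrid_split must lie in [0, 1]")

    @property
    def dimension(self) -> int:
        return self.bounds.shape[0]


@dataclass
class OptResult:
    """Outcome of one optimizer run."""

    best: Candidate
    history: List[float]  # best-so-far fitness after each iteration
    positions: np.ndarray  # final population positions (pop, D)
    fitnesses: np.ndarray  # final population fitnesses (pop,)
    n_evals: int


def _safe_eval(objective: Objective, x: np.ndarray) -> float:
    value = float(objective(x))
    if not np.isfinite(value):
        logger.warning("objective returned non-finite value at %s; assigning +inf", x)
        return float("inf")
    return value


def _eval_population(objective: Objective, positions: np.ndarray) -> np.ndarray:
    return np.array([_safe_eval(objective, p) for p in positions])


def _clamp(positions: np.ndarray, bounds: np.ndarray) -> np.ndarray:
    return np.clip(positions, bounds[:, 0], bounds[:, 1])


def _init_population(
    rng: np.random.Generator, config: OptimizerConfig
) -> np.ndarray:
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    return rng.uniform(lo, hi, size=(config.population, config.dimension))


def _pso_loop(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator,
    iterations: int,
    positions: np.ndarray,
    fitnesses: np.ndarray,
    warm: bool = False,
) -> Tuple[OptResult, int]:
    s = config.pso
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    ranges = hi - lo
    vmax = s.velocity_clamp * ranges

    # a warm-started swarm keeps its refined positions: zero initial
    # velocities, so the cognitive/social pull (not random momentum)
    # drives the refinement
    if warm:
        velocities = np.zeros_like(positions)
    else:
        velocities = rng.uniform(-vmax, vmax, size=positions.shape)
    pbest_pos = positions.copy()
    pbest_fit = fitnesses.copy()
    g = int(np.argmin(pbest_fit))
    history: List[float] = []
    evals = 0

    for _ in range(iterations):
        r1 = rng.random(positions.shape)
        r2 = rng.random(positions.shape)
        velocities = (
            s.inertia * velocities
            + s.cognitive * r1 * (pbest_pos - positions)
            + s.social * r2 * (pbest_pos[g] - positions)
        )
        velocities = np.clip(velocities, -vmax, vmax)
        positions = _clamp(positions + velocities, config.bounds)
        fitnesses = _eval_population(objective, positions)
        evals += config.population
        improved = fitnesses < pbest_fit
        pbest_pos[improved] = positions[improved]
        pbest_fit[improved] = fitnesses[improved]
        g = int(np.argmin(pbest_fit))
        history.append(float(pbest_fit[g]))

    best = Candidate(position=pbest_pos[g].copy(), fitness=float(pbest_fit[g]))
    return (
        OptResult(best=best, history=history, positions=positions,
                  fitnesses=fitnesses, n_evals=evals),
        evals,
    )


def _tso_loop(
    objective: Objective,
    config: OptimizerConfig,
    rng: np.random.Generator,
    iterations: int,
    positions: np.ndarray,
    fitnesses: np.ndarray,
) -> Tuple[OptResult, int]:
    s = config.tso
    lo, hi = config.bounds[:, 0], config.bounds[:, 1]
    ranges = hi - lo

    best_idx = int(np.argmin(fitnesses))
    best_pos = positions[best_idx].copy()
    best_fit = float(fitnesses[best_idx])
    radius = s.initial_radius
    history: List[float] = []
    evals = 0

    for _ in range(iterations):
        proposals = np.empty_like(positions)
        for i in range(config.population):
            u = rng.random()
            if u < s.exploration_fraction:
                # transit: probe between self and the global best, plus
                # heavy-tailed noise to keep long jumps possible
                step = rng.random()
                noise = s.perturbation_scale * ranges * rng.standard_cauchy(
                    config.dimension
                )
                proposals[i] = positions[i] + step * (best_pos - positions[i]) + noise
            elif u < s.exploration_fraction + s.neighbor_fraction:
                # neighbor: per-coordinate recombination with another host
                j = int(rng.integers(config.population))
                mix = rng.random(config.dimension)
                proposals[i] = positions[i] + mix * (positions[j] - positions[i])
            else:
                # exploitation: shrinking Gaussian ball around the best
                proposals[i] = best_pos + radius * ranges * rng.normal(
                    size=config.dimension
                )
        proposals = _clamp(proposals, config.bounds)
        prop_fit = _eval_population(objective, proposals)
        evals += config.population
        improved = prop_fit < fitnesses
        positions[improved] = proposals[improved]
        fitnesses[improved] = prop_fit[improved]
        i_best = int(np.argmin(fitnesses))
        if fitnesses[i_best] < best_fit:  # elitism
            best_fit = float(fitnesses[i_best])
            best_pos = positions[i_best].copy()
        radius *= s.shrink_rate
        history.append(best_fit)

    best = Candidate(position=best_pos, fitness=best_fit)
    return (
        OptResult(best=best, history=history, positions=positions,
                  fitnesses=fitnesses, n_evals=evals),
        evals,
    )


def run_pso(
    objective: Objective,
    config: OptimizerConfig,
    warm_start: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> OptResult:
    """Standard inertia-weight PSO.  ``warm_start`` is an optional
    (positions, fitnesses) pair; otherwise the swarm is uniform-random."""
    rng = np.random.default_rng(config.seed)
    if warm_start is None:
        positions = _init_population(rng, config)
        fitnesses = _eval_population(objective, positions)
        init_evals = config.population
    else:
        positions, fitnesses = warm_start[0].copy(), warm_start[1].copy()
        init_evals = 0
    result, _ = _pso_loop(
        objective, config, rng, config.iterations, positions, fitnesses,
        warm=warm_start is not None,
    )
    result.n_evals += init_evals
    logger.info("PSO: %d evals, best fitness %.6g", result.n_evals, result.best.fitness)
    return result


def run_tso(objective: Objective, config: OptimizerConfig) -> OptResult:
    """Transit-search-style global explorer (documented scheme above)."""
    rng = np.random.default_rng(config.seed)
    positions = _init_population(rng, config)
    fitnesses = _eval_population(objective, positions)
    result, _ = _tso_loop(
        objective, config, rng, config.iterations, positions, fitnesses
    )
    result.n_evals += config.population
    logger.info("TSO: %d evals, best fitness %.6g", result.n_evals, result.best.fitness)
    return result


def run_hybrid(objective: Objective, config: OptimizerConfig) -> OptResult:
    """Sequential TSO -> PSO hybrid.

    TSO runs for ``round(hybrid_split * iterations)`` iterations; its
    final population (best candidate included) seeds the PSO swarm, which
    runs the remainder.  Elitism across the hand-off guarantees the final
    best is no worse than the TSO-phase best.
    """
    rng = np.random.default_rng(config.seed)
    tso_iters = int(round(config.hybrid_split * config.iterations))
    pso_iters = config.iterations - tso_iters

    positions = _init_population(rng, config)
    fitnesses = _eval_population(objective, positions)
    evals = config.population
    history: List[float] = []

    if tso_iters > 0:
        tso_result, tso_evals = _tso_loop(
            objective, config, rng, tso_iters, positions, fitnesses
        )
        evals += tso_evals
        history.extend(tso_result.history)
        positions, fitnesses = tso_result.positions, tso_result.fitnesses
        # hand-off: make sure the elitist best candidate is in the swarm
        worst = int(np.argmax(fitnesses))
        if tso_result.best.fitness < fitnesses.min():
            positions[worst] = tso_result.best.position
            fitnesses[worst] = tso_result.best.fitness
        stage_best = tso_result.best
    else:
        b = int(np.argmin(fitnesses))
        stage_best = Candidate(position=positions[b].copy(), fitness=float(fitnesses[b]))

    if pso_iters > 0:
        pso_result, pso_evals = _pso_loop(
            objective, config, rng, pso_iters, positions, fitnesses, warm=True
        )
        evals += pso_evals
        history.extend(pso_result.history)
        positions, fitnesses = pso_result.positions, pso_result.fitnesses
        best = (
            pso_result.best
            if pso_result.best.fitness <= stage_best.fitness
            else stage_best
        )
    else:
        best = stage_best

    logger.info("hybrid: %d evals, best fitness %.6g", evals, best.fitness)
    return OptResult(
        best=best, history=history, positions=positions,
        fitnesses=fitnesses, n_evals=evals,
    )
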