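"""Real-coded genetic algorithm over a box of coded factors.

Generational GA in the GGAP tradition: linear-ranking selection with
stochastic universal sampling, arithmetic (blend) crossover, per-gene
uniform-reset mutation, and a generation gap — the fraction of the
population replaced by offspring each generation, the complement surviving
as elites.  The reference configuration is population 40, 100 generations,
crossover probability 0.7, mutation probability 0.1 and generation gap
0.95 (2 of 40 elites).  Chromosomes are real vectors in the coded factor
box; every operator is closed over the box, so no clamping is needed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import SurrogateModel, predict_ann
from .design import FactorSpec
from .optimize import Optimum

logger = logging.getLogger("extraopt.ga")

#: selective pressure of linear ranking (best expects sp offspring, worst 2-sp)
SELECTION_PRESSURE = 2.0


class FitnessDomainError(ValueError):
    """Fitness returned a non-finite value; ``point`` is the offender."""

    def __init__(self, point: np.ndarray):
        self.point = np.asarray(point)
        super().__init__(f"non-finite fitness at point {self.point.tolist()}")


@dataclass(frozen=True)
class GaConfig:
    population_size: int = 40
    generations: int = 100
    crossover_prob: float = 0.7
    mutation_prob: float = 0.1
    generation_gap: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population size must be >= 2")
        for name in ("crossover_prob", "mutation_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.generation_gap <= 1:
            raise ValueError("generation gap must be in (0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")

    @property
    def n_offspring(self) -> int:
        return max(1, int(round(self.generation_gap * self.population_size)))

    @property
    def n_elite(self) -> int:
        return self.population_size - self.n_offspring

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "generations": self.generations,
            "crossover_prob": self.crossover_prob,
            "mutation_prob": self.mutation_prob,
            "generation_gap": self.generation_gap,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaConfig":
        return cls(**d)


@dataclass
class GaResult:
    best_point: np.ndarray
    best_fitness: float
    trajectory: pd.DataFrame   # columns: generation, best, mean
    generations_run: int


def _evaluate(fitness, pop: np.ndarray) -> np.ndarray:
    vals = np.asarray(fitness(pop), dtype=float).reshape(-1)
    if vals.shape[0] != pop.shape[0]:
        raise ValueError("fitness must return one value per individual")
    bad = ~np.isfinite(vals)
    if np.any(bad):
        raise FitnessDomainError(pop[np.argmax(bad)])
    return vals


def _sus(expected: np.ndarray, n_select: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: n_select indices with equally spaced
    pointers over the cumulative expected-value wheel."""
    cum = np.cumsum(expected)
    total = cum[-1]
    pointers = (rng.uniform(0, 1) + np.arange(n_select)) / n_select * total
    return np.searchsorted(cum, pointers, side="right").clip(max=len(expected) - 1)


def run_ga(fitness, bounds, config: GaConfig | None = None) -> GaResult:
    """Maximize ``fitness`` (callable on an (n, k) array of points, returning
    (n,) values) over a (k, 2) box.

    Generation 0 is the uniformly random initial population; each later
    generation keeps the ``n_elite`` fittest individuals and replaces the
    rest with offspring from ranking selection, blend crossover and
    uniform-reset mutation.  With at least one elite the per-generation best
    fitness is monotonically non-decreasing.  Fully deterministic given the
    seed, the config and the fitness.
    """
    cfg = config or GaConfig()
    bounds = np.atleast_2d(np.asarray(bounds, dtype=float))
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must be a (k, 2) array")
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("bounds must satisfy low <= high")
    k = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(cfg.seed)
    n = cfg.population_size

    pop = rng.uniform(lo, hi, size=(n, k))
    vals = _evaluate(fitness, pop)
    traj = {"generation": [0], "best": [float(vals.max())],
            "mean": [float(vals.mean())]}
    best_i = int(vals.argmax())
    best_point, best_fitness = pop[best_i].copy(), float(vals[best_i])

    n_off = cfg.n_offspring
    for gen in range(1, cfg.generations + 1):
        order = np.argsort(vals)                      # ascending fitness
        rank = np.empty(n)
        rank[order] = np.arange(n)
        sp = SELECTION_PRESSURE
        expected = (2.0 - sp) + 2.0 * (sp - 1.0) * rank / (n - 1)

        parents = pop[_sus(expected, n_off, rng)]
        rng.shuffle(parents, axis=0)

        offspring = parents.copy()
        for a in range(0, n_off - 1, 2):
            if rng.uniform() < cfg.crossover_prob:
                alpha = rng.uniform(size=k)
                p1, p2 = parents[a].copy(), parents[a + 1].copy()
                offspring[a] = alpha * p1 + (1 - alpha) * p2
                offspring[a + 1] = alpha * p2 + (1 - alpha) * p1

        mutate = rng.uniform(size=(n_off, k)) < cfg.mutation_prob
        resets = rng.uniform(lo, hi, size=(n_off, k))
        offspring = np.where(mutate, resets, offspring)

        elites = pop[order[::-1][:cfg.n_elite]]
        elite_vals = vals[order[::-1][:cfg.n_elite]]
        off_vals = _evaluate(fitness, offspring)
        pop = np.vstack([elites, offspring]) if cfg.n_elite else offspring
        vals = np.concatenate([elite_vals, off_vals]) if cfg.n_elite else off_vals

        traj["generation"].append(gen)
        traj["best"].append(float(vals.max()))
        traj["mean"].append(float(vals.mean()))
        gi = int(vals.argmax())
        if vals[gi] > best_fitness:
            best_point, best_fitness = pop[gi].copy(), float(vals[gi])

    return GaResult(best_point=best_point, best_fitness=best_fitness,
                    trajectory=pd.DataFrame(traj),
                    generations_run=cfg.generations)


def optimize_ann_ga(model: SurrogateModel, factors: list[FactorSpec],
                    bounds=None, config: GaConfig | None = None) -> Optimum:
    """GA maximization of the trained surrogate over the coded box.

    Returns the best point decoded to actual units with the per-generation
    fitness trajectory attached for export.
    """
    k = len(factors)
    bounds = np.tile([-1.0, 1.0], (k, 1)) if bounds is None \
        else np.atleast_2d(np.asarray(bounds, dtype=float))
    result = run_ga(lambda pts: predict_ann(model, pts), bounds, config)
    actual = np.array([f.decode(x) for f, x in zip(factors, result.best_point)])
    return Optimum(coded=result.best_point, actual=actual,
                   predicted_response=result.best_fitness,
                   method="ANN-GA", converged=True,
                   trajectory=result.trajectory)
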