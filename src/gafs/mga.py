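"""Matrix-structured genetic algorithm (MGA).

The population is a 2-D grid of individuals rather than a flat list.  Each
generation: the best individual of every row is marked (first occurrence on
ties), copied onto that row's main-diagonal slot ("diagonal dominance", only
defined for square grids), every off-diagonal cell is crossed with its row's
diagonal individual at the crossover rate, offspring genes mutate at the
mutation rate, fitness is re-evaluated, and the global best survives
unchanged (elitism), so best-so-far fitness is monotone non-increasing.

Two chromosome modes share the engine:

* continuous — real vectors within per-dimension bounds; crossover is an
  arithmetic blend with uniform alpha, mutation a clipped Gaussian
  perturbation with sigma = 10% of the bound width;
* binary — bit masks; uniform crossover and bit-flip mutation.

Minimization is the single convention: wrappers that maximize accuracy feed
the engine 1 − accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "OptimizationProblem",
    "MatrixPopulation",
    "GAConfig",
    "MGAResult",
    "init_population",
    "step",
    "minimize",
    "benchmark_suite",
    "simple_ga_minimize",
]


@dataclass
class OptimizationProblem:
    """A minimization problem over a continuous box or binary strings.

    ``bounds`` is an array of shape (dims, 2) for continuous mode, or None
    for binary chromosomes of length ``dims``.  ``initializer``, when given,
    draws one individual from a custom distribution (used e.g. for
    Gaussian-initialized weight chromosomes).
    """

    objective: Callable[[np.ndarray], float]
    dims: int
    bounds: np.ndarray | None = None
    initializer: Callable[[np.random.Generator], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.dims < 1:
            raise ValueError("dims must be >= 1")
        if self.bounds is not None:
            b = np.asarray(self.bounds, dtype=float)
            if b.shape != (self.dims, 2):
                raise ValueError("bounds must have shape (dims, 2)")
            if np.any(b[:, 0] > b[:, 1]):
                raise ValueError("infeasible bounds: lower > upper")
            self.bounds = b

    @property
    def mode(self) -> str:
        return "binary" if self.bounds is None else "continuous"


@dataclass
class GAConfig:
    """Grid shape, operator rates, termination.

    ``mutation_rate=None`` resolves to the per-gene default 1/dims.  The
    default 5×5 grid gives the classic population structure of 25.
    """

    rows: int = 5
    cols: int = 5
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float | None = None
    seed: int = 0
    tol: float | None = None

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1 or self.rows * self.cols < 2:
            raise ValueError("grid must contain at least 2 individuals")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")

    def resolve_mutation_rate(self, dims: int) -> float:
        return self.mutation_rate if self.mutation_rate is not None else 1.0 / dims


@dataclass
class MatrixPopulation:
    """R×C grid of chromosomes with fitness, row-best marks and a generation counter."""

    grid: np.ndarray          # (R, C, dims)
    fitness: np.ndarray       # (R, C)
    row_best: np.ndarray      # (R,) column index, first occurrence on ties
    generation: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.fitness.shape

    @property
    def is_square(self) -> bool:
        r, c = self.shape
        return r == c

    def global_best(self) -> tuple[np.ndarray, float]:
        i, j = np.unravel_index(int(np.argmin(self.fitness)), self.fitness.shape)
        return self.grid[i, j].copy(), float(self.fitness[i, j])


@dataclass
class MGAResult:
    best_x: np.ndarray
    best_f: float
    history: list[float] = field(default_factory=list)


def _row_best(fitness: np.ndarray) -> np.ndarray:
    return np.argmin(fitness, axis=1)  # argmin returns the first occurrence


def _evaluate(problem: OptimizationProblem, grid: np.ndarray) -> np.ndarray:
    r, c, _ = grid.shape
    fit = np.empty((r, c))
    for i in range(r):
        for j in range(c):
            fit[i, j] = problem.objective(grid[i, j])
    if not np.all(np.isfinite(fit)):
        raise ValueError("objective returned a non-finite value")
    return fit


def init_population(problem: OptimizationProblem, cfg: GAConfig,
                    rng: np.random.Generator | None = None) -> MatrixPopulation:
    """Seeded random grid: uniform within bounds, Bernoulli(0.5) bits, or a
    custom initializer; fitness evaluated and row bests marked."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    r, c, d = cfg.rows, cfg.cols, problem.dims
    if problem.initializer is not None:
        grid = np.stack([
            np.stack([np.asarray(problem.initializer(rng), dtype=float)
                      for _ in range(c)])
            for _ in range(r)
        ])
        if grid.shape != (r, c, d):
            raise ValueError("initializer returned wrong-length individual")
    elif problem.mode == "binary":
        grid = rng.integers(0, 2, size=(r, c, d)).astype(float)
    else:
        lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
        grid = rng.uniform(lo, hi, size=(r, c, d))
    fitness = _evaluate(problem, grid)
    return MatrixPopulation(grid, fitness, _row_best(fitness), generation=0)


def _crossover(child: np.ndarray, partner: np.ndarray,
               problem: OptimizationProblem, rng: np.random.Generator) -> np.ndarray:
    if problem.mode == "binary":
        mask = rng.random(problem.dims) < 0.5
        out = child.copy()
        out[mask] = partner[mask]
        return out
    alpha = rng.random()
    return alpha * child + (1.0 - alpha) * partner


def _mutate(child: np.ndarray, problem: OptimizationProblem,
            mut_rate: float, rng: np.random.Generator) -> np.ndarray:
    mask = rng.random(problem.dims) < mut_rate
    if not mask.any():
        return child
    out = child.copy()
    if problem.mode == "binary":
        out[mask] = 1.0 - out[mask]
    else:
        lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
        sigma = 0.1 * (hi - lo)
        out[mask] = out[mask] + rng.normal(0.0, 1.0, int(mask.sum())) * sigma[mask]
        out = np.clip(out, lo, hi)
    return out


def step(pop: MatrixPopulation, problem: OptimizationProblem, cfg: GAConfig,
         rng: np.random.Generator) -> MatrixPopulation:
    """One generation of the diagonal-dominant cycle; global best never worsens."""
    r, c = pop.shape
    elite_x, elite_f = pop.global_best()
    row_best = _row_best(pop.fitness)
    square = pop.is_square
    if not square and pop.generation == 0:
        warnings.warn("non-square grid: diagonal dominance disabled (row-best only)",
                      stacklevel=2)

    grid = pop.grid.copy()
    fitness = pop.fitness.copy()
    # (2) copy each row's best onto that row's main-diagonal slot
    if square:
        for i in range(r):
            grid[i, i] = pop.grid[i, row_best[i]]
            fitness[i, i] = pop.fitness[i, row_best[i]]

    mut_rate = cfg.resolve_mutation_rate(problem.dims)
    for i in range(r):
        partner = grid[i, i] if square else pop.grid[i, row_best[i]]
        for j in range(c):
            if square and j == i:
                continue  # the diagonal keeps the row-best copy
            child = pop.grid[i, j]
            changed = False
            if rng.random() < cfg.crossover_rate:
                child = _crossover(child, partner, problem, rng)
                changed = True
            mutated = _mutate(child, problem, mut_rate, rng)
            changed = changed or mutated is not child
            grid[i, j] = mutated
            if changed:
                fitness[i, j] = problem.objective(mutated)

    # (6) elitism: the incoming global best survives unchanged
    if fitness.min() > elite_f:
        wi, wj = np.unravel_index(int(np.argmax(fitness)), fitness.shape)
        grid[wi, wj] = elite_x
        fitness[wi, wj] = elite_f
    return MatrixPopulation(grid, fitness, _row_best(fitness),
                            generation=pop.generation + 1)


def minimize(problem: OptimizationProblem, cfg: GAConfig) -> MGAResult:
    """Run init + steps until the generation budget or fitness tolerance is met.

    ``history[g]`` is the best fitness after g generations (index 0 = initial
    population); it is non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    pop = init_population(problem, cfg, rng)
    _, best_f = pop.global_best()
    history = [best_f]
    for _ in range(cfg.generations):
        if cfg.tol is not None and best_f <= cfg.tol:
            break
        pop = step(pop, problem, cfg, rng)
        _, best_f = pop.global_best()
        history.append(best_f)
    best_x, best_f = pop.global_best()
    return MGAResult(best_x, best_f, history)


# ---------------------------------------------------------------------------
# Benchmark objectives (standard closed forms with global minimum 0)
# ---------------------------------------------------------------------------

def benchmark_suite(name: str, dims: int) -> OptimizationProblem:
    """Standard continuous test functions: sphere, rastrigin, rosenbrock."""
    if not 1 <= dims <= 30:
        raise ValueError("dims must be in [1, 30]")
    if name == "sphere":
        bounds = np.tile([-5.12, 5.12], (dims, 1))
        return OptimizationProblem(lambda x: float(np.sum(x ** 2)), dims, bounds)
    if name == "rastrigin":
        bounds = np.tile([-5.12, 5.12], (dims, 1))

        def rastrigin(x: np.ndarray) -> float:
            return float(10 * dims + np.sum(x ** 2 - 10 * np.cos(2 * np.pi * x)))

        return OptimizationProblem(rastrigin, dims, bounds)
    if name == "rosenbrock":
        bounds = np.tile([-2.048, 2.048], (dims, 1))

        def rosenbrock(x: np.ndarray) -> float:
            if len(x) < 2:
                return float((1 - x[0]) ** 2)
            return float(np.sum(100 * (x[1:] - x[:-1] ** 2) ** 2
                                + (1 - x[:-1]) ** 2))

        return OptimizationProblem(rosenbrock, dims, bounds)
    raise ValueError(f"unknown benchmark {name!r}")


# ---------------------------------------------------------------------------
# Plain single-population GA baseline (for convergence-ordering comparisons)
# ---------------------------------------------------------------------------

def simple_ga_minimize(problem: OptimizationProblem, cfg: GAConfig) -> MGAResult:
    """Flat-population GA with random-mate crossover; same operators and
    budget as the matrix engine, used as a comparison baseline."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.rows * cfg.cols
    mut_rate = cfg.resolve_mutation_rate(problem.dims)
    if problem.initializer is not None:
        pop = np.stack([np.asarray(problem.initializer(rng), dtype=float)
                        for _ in range(n)])
    elif problem.mode == "binary":
        pop = rng.integers(0, 2, size=(n, problem.dims)).astype(float)
    else:
        lo, hi = problem.bounds[:, 0], problem.bounds[:, 1]
        pop = rng.uniform(lo, hi, size=(n, problem.dims))
    fit = np.array([problem.objective(x) for x in pop])
    best_i = int(np.argmin(fit))
    best_x, best_f = pop[best_i].copy(), float(fit[best_i])
    history = [best_f]
    for _ in range(cfg.generations):
        for j in range(n):
            child = pop[j]
            if rng.random() < cfg.crossover_rate:
                mate = pop[rng.integers(n)]
                child = _crossover(child, mate, problem, rng)
            child = _mutate(child, problem, mut_rate, rng)
            f = problem.objective(child)
            pop[j], fit[j] = child, f
        if fit.min() > best_f:
            wi = int(np.argmax(fit))
            pop[wi], fit[wi] = best_x, best_f
        bi = int(np.argmin(fit))
        if fit[bi] < best_f:
            best_x, best_f = pop[bi].copy(), float(fit[bi])
        history.append(best_f)
    return MGAResult(best_x, best_f, history)
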