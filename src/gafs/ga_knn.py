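"""GA-KNN wrapper feature selection.

A chromosome assigns one weight per feature under one of five encoding
schemes (binary, decimal, real, gaussian, adaptive).  Decoding keeps the
features whose weight exceeds a threshold; the fitness of a chromosome is
the validation accuracy of a KNN classifier using the weighted Minkowski
distance restricted to the decoded subset — so the weights shape the
classifier's geometry, not just subset membership.  The matrix-structured GA
engine evolves the population, minimizing 1 − accuracy; elitism makes the
best-so-far validation accuracy non-decreasing.

Encoding schemes (the decode/initialization rules are this package's
recorded interpretation — only the scheme names are standard):

* binary   — bits in {0, 1}; threshold 0.5 (decode∘encode is the identity).
* decimal  — weights quantized to {0.0, 0.1, …, 1.0}; threshold 0.5.
* real     — weights free in [0, 1]; threshold 0.5.
* gaussian — like real, but initialized from N(0.5, 0.2) clipped to [0, 1].
* adaptive — like real, but the threshold tracks the mean weight of the
  current best individual each generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LabeledDataset, stratified_split
from .knn import DEFAULT_K, DistanceSpec, evaluate_knn
from .mga import GAConfig, MatrixPopulation, OptimizationProblem, init_population, step

__all__ = [
    "SCHEMES",
    "WeightChromosome",
    "SelectionResult",
    "decode",
    "fitness",
    "select_features",
    "report",
]

SCHEMES = ("binary", "decimal", "real", "gaussian", "adaptive")


@dataclass
class WeightChromosome:
    """Per-feature weight vector under one encoding scheme."""

    scheme: str
    weights: np.ndarray
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if self.scheme == "binary" and not np.all(np.isin(w, (0.0, 1.0))):
            raise ValueError("binary scheme requires weights in {0, 1}")
        if self.scheme == "decimal" and not np.allclose(w * 10, np.round(w * 10)):
            raise ValueError("decimal scheme requires weights in {0, 0.1, ..., 1.0}")
        self.weights = w


@dataclass
class SelectionResult:
    """Outcome of one wrapper run: subset, before/after accuracy, history."""

    scheme: str
    best_chromosome: WeightChromosome
    selected: set[int]
    n_before: int
    n_after: int
    acc_before: float
    acc_after: float
    history: list[float] = field(default_factory=list)  # best accuracy per generation


def _quantize(weights: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "binary":
        return np.round(weights)
    if scheme == "decimal":
        return np.round(weights * 10) / 10.0
    return weights


def decode(chrom: WeightChromosome) -> set[int]:
    """Feature indices with weight strictly above the threshold."""
    return set(np.flatnonzero(chrom.weights > chrom.threshold).tolist())


def fitness(chrom: WeightChromosome, train: LabeledDataset, val: LabeledDataset,
            k: int = DEFAULT_K, p: float = 2.0) -> float:
    """Validation KNN accuracy under the chromosome's weighted geometry.

    The distance is the weighted Minkowski metric restricted to the decoded
    subset, with the chromosome's weights on those coordinates.  An empty
    subset scores 0 (the evolution handles degenerate chromosomes).
    """
    sel = sorted(decode(chrom))
    if not sel:
        return 0.0
    spec = DistanceSpec(kind="minkowski", p=p, weights=chrom.weights[sel])
    return evaluate_knn(train.take_features(sel), val.take_features(sel), k, spec)


def _make_problem(ds_dims: int, scheme: str, rng_init_sd: float = 0.2
                  ) -> OptimizationProblem:
    if scheme == "binary":
        return OptimizationProblem(lambda w: 0.0, ds_dims, bounds=None)
    bounds = np.tile([0.0, 1.0], (ds_dims, 1))
    initializer = None
    if scheme == "gaussian":
        def initializer(rng: np.random.Generator) -> np.ndarray:
            return np.clip(rng.normal(0.5, rng_init_sd, ds_dims), 0.0, 1.0)
    return OptimizationProblem(lambda w: 0.0, ds_dims, bounds=bounds,
                               initializer=initializer)


def select_features(ds: LabeledDataset, scheme: str = "binary",
                    ga_cfg: GAConfig | None = None, k: int = DEFAULT_K,
                    seed: int | None = None, train_fraction: float = 0.7,
                    ) -> SelectionResult:
    """Evolve weight chromosomes maximizing internal validation accuracy.

    The dataset is split once (stratified, seeded, default 70/30) into an
    internal train/validation pair; every chromosome is scored on the same
    split.  Returns the decoded best subset together with the accuracy of
    the all-features chromosome (``acc_before``) for the standard
    before/after report.
    """
    if ds.has_missing:
        raise ValueError("select_features requires a complete matrix; impute first")
    ds.require_classification()
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    ga_cfg = ga_cfg if ga_cfg is not None else GAConfig(generations=40)
    if seed is not None:
        ga_cfg = GAConfig(rows=ga_cfg.rows, cols=ga_cfg.cols,
                          generations=ga_cfg.generations,
                          crossover_rate=ga_cfg.crossover_rate,
                          mutation_rate=ga_cfg.mutation_rate,
                          seed=seed, tol=ga_cfg.tol)

    train, val = stratified_split(ds, train_fraction, seed=ga_cfg.seed)
    d = ds.n_features
    state = {"threshold": 0.5}

    def objective(w: np.ndarray) -> float:
        wq = _quantize(np.asarray(w, dtype=float), scheme)
        chrom = WeightChromosome(scheme, wq, threshold=state["threshold"])
        return 1.0 - fitness(chrom, train, val, k=k)

    problem = _make_problem(d, scheme)
    problem.objective = objective

    rng = np.random.default_rng(ga_cfg.seed)
    pop: MatrixPopulation = init_population(problem, ga_cfg, rng)
    best_x, best_f = pop.global_best()
    history = [1.0 - best_f]
    for _ in range(ga_cfg.generations):
        if scheme == "adaptive":
            state["threshold"] = float(np.mean(_quantize(best_x, scheme)))
        pop = step(pop, problem, ga_cfg, rng)
        x, f = pop.global_best()
        if f < best_f:           # keep the historical best under a moving threshold
            best_x, best_f = x, f
        history.append(1.0 - best_f)

    best_w = _quantize(best_x, scheme)
    best_chrom = WeightChromosome(scheme, best_w, threshold=state["threshold"])
    selected = decode(best_chrom)

    all_features = WeightChromosome(scheme, np.ones(d) if scheme != "decimal"
                                    else np.ones(d), threshold=0.5)
    acc_before = fitness(all_features, train, val, k=k)
    acc_after = 1.0 - best_f
    return SelectionResult(
        scheme=scheme,
        best_chromosome=best_chrom,
        selected=selected,
        n_before=d,
        n_after=len(selected),
        acc_before=acc_before,
        acc_after=acc_after,
        history=history,
    )


def report(results: "SelectionResult | list[SelectionResult]") -> pd.DataFrame:
    """Before/after summary table, one row per run.

    Columns: scheme, features before, recognition rate before, features
    after, recognition rate after (rates rounded to 4 decimals, the
    conventional reporting precision).
    """
    if isinstance(results, SelectionResult):
        results = [results]
    rows = [
        {
            "scheme": r.scheme,
            "n_before": r.n_before,
            "acc_before": round(r.acc_before, 4),
            "n_after": r.n_after,
            "acc_after": round(r.acc_after, 4),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["scheme", "n_before", "acc_before",
                                       "n_after", "acc_after"])
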