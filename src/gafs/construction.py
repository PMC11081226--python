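"""Genetic-programming feature construction.

New features are arithmetic expression trees over a selected feature subset:
internal nodes come from the function set {+, −, ×, ÷}, leaves are feature
indices or ephemeral random constants.  Division is protected (x ÷ y = 1
when |y| < 1e-9) and every node's output is clamped to a large finite range,
so tree evaluation is total and finite on any real input.

Evolution uses tournament ("championship") selection with subtree crossover,
subtree mutation and reproduction chosen per offspring with probabilities
proportional to the configured rates, a hard depth cap (offspring violating
it are rejected and the parent retained) and elitism of one.  The fitness of
a tree is the validation accuracy of a KNN classifier on the data with the
tree's output appended as one extra standardized column — a constructed
feature is only as good as the class structure it exposes to the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset, SIGMA_FLOOR
from .knn import DEFAULT_K, DistanceSpec, evaluate_knn

__all__ = [
    "ExpressionTree",
    "GPConfig",
    "evaluate_tree",
    "random_tree",
    "construct_feature",
    "construct_multi",
    "validate_constructed",
    "augment_dataset",
]

_OPS = ("+", "-", "*", "/")
_DIV_EPS = 1e-9
_CLAMP = 1e100  # per-node output clamp keeping deep products finite
_CONST_FRACTION = 0.1  # fraction of leaf draws that are ephemeral constants


# Nodes are nested tuples: ("op", op, left, right) | ("f", index) | ("c", value)

@dataclass
class ExpressionTree:
    """Binary arithmetic tree over feature indices and constants."""

    root: tuple
    max_depth: int = 19

    def __post_init__(self) -> None:
        if self.depth > self.max_depth:
            raise ValueError(f"tree depth {self.depth} exceeds bound {self.max_depth}")

    @property
    def depth(self) -> int:
        return _depth(self.root)

    @property
    def size(self) -> int:
        return _size(self.root)

    def __str__(self) -> str:
        return _to_string(self.root)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        """Vectorized evaluation over the rows of X (shape (N, D) -> (N,))."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        max_leaf = _max_feature(self.root)
        if max_leaf >= X.shape[1]:
            raise ValueError(
                f"tree references feature {max_leaf} but input has {X.shape[1]}")
        return _eval(self.root, X)


def _depth(node: tuple) -> int:
    if node[0] != "op":
        return 1
    return 1 + max(_depth(node[2]), _depth(node[3]))


def _size(node: tuple) -> int:
    if node[0] != "op":
        return 1
    return 1 + _size(node[2]) + _size(node[3])


def _max_feature(node: tuple) -> int:
    if node[0] == "f":
        return node[1]
    if node[0] == "c":
        return -1
    return max(_max_feature(node[2]), _max_feature(node[3]))


def _to_string(node: tuple) -> str:
    if node[0] == "f":
        return f"f{node[1]}"
    if node[0] == "c":
        return f"{node[1]:.6g}"
    return f"({_to_string(node[2])} {node[1]} {_to_string(node[3])})"


def _eval(node: tuple, X: np.ndarray) -> np.ndarray:
    kind = node[0]
    if kind == "f":
        return X[:, node[1]].copy()
    if kind == "c":
        return np.full(X.shape[0], float(node[1]))
    left = _eval(node[2], X)
    right = _eval(node[3], X)
    op = node[1]
    if op == "+":
        out = left + right
    elif op == "-":
        out = left - right
    elif op == "*":
        out = left * right
    else:  # protected division: x / y = 1 when |y| is (near) zero
        safe = np.where(np.abs(right) < _DIV_EPS, 1.0, right)
        out = np.where(np.abs(right) < _DIV_EPS, 1.0, left / safe)
    return np.clip(np.nan_to_num(out, nan=1.0, posinf=_CLAMP, neginf=-_CLAMP),
                   -_CLAMP, _CLAMP)


def evaluate_tree(tree: ExpressionTree, sample) -> float:
    """Evaluate a tree on a single length-D sample (always finite)."""
    return float(tree.evaluate(np.asarray(sample, dtype=float).reshape(1, -1))[0])


@dataclass
class GPConfig:
    """Tree-GP parameters.

    The defaults are the conventional settings for this task: population 600,
    55 generations, crossover rate 1.0 with reproduction and mutation rates
    0.2 (applied per offspring as a categorical choice proportional to the
    three rates), tournament size 7, maximum tree depth 19.
    """

    population_size: int = 600
    generations: int = 55
    crossover_rate: float = 1.0
    reproduction_rate: float = 0.2
    mutation_rate: float = 0.2
    tournament_size: int = 7
    max_depth: int = 19
    runs: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "reproduction_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.population_size >= self.tournament_size >= 2:
            raise ValueError("population >= tournament_size >= 2 required")
        if self.max_depth < 2:
            raise ValueError("max_depth must be >= 2")

    @property
    def operator_probs(self) -> np.ndarray:
        rates = np.array([self.crossover_rate, self.reproduction_rate,
                          self.mutation_rate], dtype=float)
        if rates.sum() == 0:
            return np.array([0.0, 1.0, 0.0])  # pure reproduction
        return rates / rates.sum()


# ---------------------------------------------------------------------------
# Random trees (ramped half-and-half)
# ---------------------------------------------------------------------------

def _random_leaf(terminals: list[int], rng: np.random.Generator) -> tuple:
    if rng.random() < _CONST_FRACTION:
        return ("c", float(rng.uniform(-1.0, 1.0)))
    return ("f", int(terminals[rng.integers(len(terminals))]))


def _grow(depth: int, terminals: list[int], rng: np.random.Generator,
          full: bool) -> tuple:
    if depth <= 1 or (not full and rng.random() < 0.3):
        return _random_leaf(terminals, rng)
    op = _OPS[rng.integers(len(_OPS))]
    return ("op", op,
            _grow(depth - 1, terminals, rng, full),
            _grow(depth - 1, terminals, rng, full))


def random_tree(cfg: GPConfig, terminals, rng: np.random.Generator
                ) -> ExpressionTree:
    """Ramped half-and-half initialization between depth 2 and min(6, max_depth)."""
    terminals = sorted(terminals)
    if not terminals:
        raise ValueError("terminals must be nonempty")
    hi = min(6, cfg.max_depth)
    depth = int(rng.integers(2, hi + 1))
    full = bool(rng.integers(2))
    return ExpressionTree(_grow(depth, terminals, rng, full), cfg.max_depth)


# ---------------------------------------------------------------------------
# Genetic operators
# ---------------------------------------------------------------------------

def _nodes_with_paths(node: tuple, path=()) -> list[tuple]:
    out = [path]
    if node[0] == "op":
        out += _nodes_with_paths(node[2], path + (2,))
        out += _nodes_with_paths(node[3], path + (3,))
    return out


def _get(node: tuple, path) -> tuple:
    for step in path:
        node = node[step]
    return node


def _replace(node: tuple, path, sub: tuple) -> tuple:
    if not path:
        return sub
    lst = list(node)
    lst[path[0]] = _replace(node[path[0]], path[1:], sub)
    return tuple(lst)


def _subtree_crossover(a: tuple, b: tuple, rng: np.random.Generator) -> tuple:
    paths_a = _nodes_with_paths(a)
    paths_b = _nodes_with_paths(b)
    pa = paths_a[rng.integers(len(paths_a))]
    pb = paths_b[rng.integers(len(paths_b))]
    return _replace(a, pa, _get(b, pb))


def _subtree_mutation(a: tuple, terminals: list[int], cfg: GPConfig,
                      rng: np.random.Generator) -> tuple:
    paths = _nodes_with_paths(a)
    pa = paths[rng.integers(len(paths))]
    depth = int(rng.integers(1, min(4, cfg.max_depth) + 1))
    sub = _grow(depth, terminals, rng, full=False)
    return _replace(a, pa, sub)


def _tournament(fitnesses: np.ndarray, size: int,
                rng: np.random.Generator) -> int:
    idx = rng.integers(len(fitnesses), size=size)
    best = idx[0]
    for i in idx[1:]:
        if fitnesses[i] > fitnesses[best] or (
                fitnesses[i] == fitnesses[best] and i < best):
            best = i
    return int(best)


# ---------------------------------------------------------------------------
# Fitness: KNN accuracy with the tree output appended as a standardized column
# ---------------------------------------------------------------------------

def _augment_matrices(train_X: np.ndarray, other_X: np.ndarray,
                      trees: list[ExpressionTree]) -> tuple[np.ndarray, np.ndarray]:
    """Append each tree's standardized output, using train-derived statistics."""
    tr_cols, ot_cols = [train_X], [other_X]
    for tree in trees:  # trees are defined over the base features only
        tr = tree.evaluate(train_X)
        ot = tree.evaluate(other_X)
        mu = float(np.mean(tr))
        sigma = max(float(np.std(tr)), SIGMA_FLOOR)
        tr_cols.append(((tr - mu) / sigma)[:, None])
        ot_cols.append(((ot - mu) / sigma)[:, None])
    return np.hstack(tr_cols), np.hstack(ot_cols)


def augment_dataset(train: LabeledDataset, other: LabeledDataset,
                    trees: list[ExpressionTree]
                    ) -> tuple[LabeledDataset, LabeledDataset]:
    """Datasets with constructed-feature columns appended (train-fitted scaling)."""
    tr_X, ot_X = _augment_matrices(train.matrix, other.matrix, trees)
    names = list(train.feature_names) + [f"gp{i}" for i in range(len(trees))]
    tr = LabeledDataset(tr_X, train.labels.copy(), names, list(train.sample_ids))
    ot = LabeledDataset(ot_X, other.labels.copy(), names, list(other.sample_ids))
    return tr, ot


def _tree_fitness(tree: ExpressionTree, train: LabeledDataset,
                  val: LabeledDataset, k: int, spec: DistanceSpec) -> float:
    tr_X, va_X = _augment_matrices(train.matrix, val.matrix, [tree])
    tr = LabeledDataset(tr_X, train.labels)
    va = LabeledDataset(va_X, val.labels)
    return evaluate_knn(tr, va, k, spec)


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def construct_feature(train: LabeledDataset, val: LabeledDataset, terminals,
                      cfg: GPConfig, k: int = DEFAULT_K,
                      seed: int | None = None) -> tuple[ExpressionTree, float]:
    """Evolve one constructed feature; returns the best tree and its fitness."""
    if train.has_missing or val.has_missing:
        raise ValueError("construction requires complete matrices; impute first")
    terminals = sorted(terminals)
    if not terminals or max(terminals) >= train.n_features:
        raise ValueError("terminals must be a nonempty subset of the features")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    spec = DistanceSpec(kind="minkowski", p=2.0)

    pop = [random_tree(cfg, terminals, rng) for _ in range(cfg.population_size)]
    fit = np.array([_tree_fitness(t, train, val, k, spec) for t in pop])
    best_i = int(np.argmax(fit))
    best_tree, best_fit = pop[best_i], float(fit[best_i])
    probs = cfg.operator_probs

    for _ in range(cfg.generations):
        new_pop: list[ExpressionTree] = [best_tree]  # elitism of 1
        new_fit = [best_fit]
        while len(new_pop) < cfg.population_size:
            choice = int(rng.choice(3, p=probs))
            pi = _tournament(fit, cfg.tournament_size, rng)
            parent = pop[pi]
            if choice == 0:  # crossover
                mate = pop[_tournament(fit, cfg.tournament_size, rng)]
                child_root = _subtree_crossover(parent.root, mate.root, rng)
            elif choice == 1:  # reproduction
                child_root = parent.root
            else:  # subtree mutation
                child_root = _subtree_mutation(parent.root, terminals, cfg, rng)
            if _depth(child_root) > cfg.max_depth:
                child_root = parent.root  # reject over-deep offspring
            child = ExpressionTree(child_root, cfg.max_depth)
            new_pop.append(child)
            if child_root is parent.root:
                new_fit.append(float(fit[pi]))
            else:
                new_fit.append(_tree_fitness(child, train, val, k, spec))
        pop = new_pop
        fit = np.array(new_fit)
        i = int(np.argmax(fit))
        if fit[i] > best_fit:
            best_tree, best_fit = pop[i], float(fit[i])
    return best_tree, best_fit


def construct_multi(train: LabeledDataset, val: LabeledDataset, terminals,
                    cfg: GPConfig, k: int = DEFAULT_K) -> list[ExpressionTree]:
    """``cfg.runs`` independent seeded constructions; duplicate expressions removed."""
    if cfg.runs < 1:
        raise ValueError("cfg.runs must be >= 1")
    trees: list[ExpressionTree] = []
    seen: set[str] = set()
    for r in range(cfg.runs):
        tree, _ = construct_feature(train, val, terminals, cfg, k=k,
                                    seed=cfg.seed + 7919 * r)
        key = str(tree)
        if key not in seen:
            seen.add(key)
            trees.append(tree)
    return trees


def validate_constructed(train: LabeledDataset, test: LabeledDataset,
                         trees: list[ExpressionTree], k: int = DEFAULT_K
                         ) -> tuple[float, float]:
    """Test accuracy before and after appending the constructed features.

    The feature transformation (tree outputs and their scaling) is fitted on
    the training set and applied unchanged to the test set — no leakage.
    """
    spec = DistanceSpec(kind="minkowski", p=2.0)
    acc_without = evaluate_knn(train, test, k, spec)
    if not trees:
        return acc_without, acc_without
    tr, te = augment_dataset(train, test, trees)
    acc_with = evaluate_knn(tr, te, k, spec)
    return acc_without, acc_with
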