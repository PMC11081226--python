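"""Distance functions and the K-nearest-neighbour classifier.

The classifier serves two roles: a standalone evaluator and the fitness
function inside the GA wrapper.  Two metrics are supported — Chebyshev
(L_inf, the max absolute coordinate difference) and the weighted Minkowski
family

    L_p(x, y) = ( sum_l (w_l |x_l - y_l|)^p )^(1/p),   p >= 1,

where the non-negative per-feature weights w_l are how the wrapper's
"empowerment" of features changes the geometry the classifier sees.
Brute-force neighbour search is used throughout: at the sample counts this
kind of data has (tens to a few hundred rows) trees buy nothing.

Tie handling is deterministic: equal distances keep the lower training
index; vote ties go to the class whose nearest member is closest, then to
the lexicographically smallest label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset, classification_accuracy

__all__ = [
    "DistanceSpec",
    "Neighborhood",
    "distance",
    "pairwise_distances",
    "neighborhood",
    "knn_predict",
    "predict_batch",
    "evaluate_knn",
    "misclassification_rate",
    "scan_k",
    "DEFAULT_K",
]

#: Default neighbour count: odd, and the value at which the recognition-rate
#: scan over odd k typically peaks on this kind of data.
DEFAULT_K = 7

#: Default odd-k grid for the recognition-rate scan.
DEFAULT_K_GRID = (1, 3, 5, 7, 9, 11, 13, 15)


@dataclass
class DistanceSpec:
    """Metric choice: ``chebyshev`` or ``minkowski`` with exponent ``p >= 1``.

    ``weights``, when given, must be length-D non-negative with at least one
    positive entry; absent means all-ones.
    """

    kind: str = "minkowski"
    p: float = 2.0
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("chebyshev", "minkowski"):
            raise ValueError(f"unknown metric kind {self.kind!r}")
        if self.kind == "minkowski" and self.p < 1:
            raise ValueError("minkowski exponent p must be >= 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("weights must be non-negative with some positive entry")
            self.weights = w


@dataclass
class Neighborhood:
    """The k nearest training samples of one query, sorted by distance."""

    indices: np.ndarray
    distances: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.distances) < 0):
            raise ValueError("distances must be non-decreasing")
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("indices must be distinct")

    @property
    def k(self) -> int:
        return len(self.indices)


def _check_vectors(x: np.ndarray, y: np.ndarray, spec: DistanceSpec) -> np.ndarray:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of the same length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite coordinate")
    if spec.weights is not None and len(spec.weights) != len(x):
        raise ValueError("weights length mismatch")
    w = spec.weights if spec.weights is not None else np.ones(len(x))
    return w


def distance(x, y, spec: DistanceSpec) -> float:
    """Weighted distance between two complete vectors under ``spec``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = _check_vectors(x, y, spec)
    d = w * np.abs(x - y)
    if spec.kind == "chebyshev":
        return float(np.max(d)) if d.size else 0.0
    return float(np.sum(d ** spec.p) ** (1.0 / spec.p))


def pairwise_distances(X: np.ndarray, Q: np.ndarray, spec: DistanceSpec,
                       block: int = 64) -> np.ndarray:
    """Distances from each query row of Q to each training row of X.

    Returns an (n_queries, n_train) array; queries are processed in blocks to
    bound memory on wide matrices.
    """
    X = np.asarray(X, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if X.ndim != 2 or Q.ndim != 2 or X.shape[1] != Q.shape[1]:
        raise ValueError("X and Q must be 2-D with matching feature counts")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Q))):
        raise ValueError("non-finite coordinate (impute missing values first)")
    w = spec.weights if spec.weights is not None else None
    if w is not None and len(w) != X.shape[1]:
        raise ValueError("weights length mismatch")
    out = np.empty((Q.shape[0], X.shape[0]))
    for s in range(0, Q.shape[0], block):
        q = Q[s:s + block]
        diff = np.abs(q[:, None, :] - X[None, :, :])
        if w is not None:
            diff = diff * w
        if spec.kind == "chebyshev":
            out[s:s + block] = diff.max(axis=2) if diff.shape[2] else 0.0
        else:
            out[s:s + block] = (diff ** spec.p).sum(axis=2) ** (1.0 / spec.p)
    return out


def _sorted_order(dists: np.ndarray) -> np.ndarray:
    # stable sort: equal distances keep the lower training index
    return np.argsort(dists, kind="stable")


def neighborhood(train: LabeledDataset, query, k: int,
                 spec: DistanceSpec) -> Neighborhood:
    """The k nearest training samples of ``query`` (deterministic ties)."""
    if not 1 <= k <= train.n_samples:
        raise ValueError(f"k={k} out of range [1, {train.n_samples}]")
    q = np.asarray(query, dtype=float).reshape(1, -1)
    dists = pairwise_distances(train.matrix, q, spec)[0]
    order = _sorted_order(dists)[:k]
    return Neighborhood(order, dists[order], train.labels[order])


def _vote(nb_labels: np.ndarray, nb_dists: np.ndarray) -> str:
    counts: dict[str, int] = {}
    nearest: dict[str, float] = {}
    for lab, d in zip(nb_labels, nb_dists):
        counts[lab] = counts.get(lab, 0) + 1
        if lab not in nearest:
            nearest[lab] = float(d)  # first occurrence is the nearest (sorted)
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    return min(tied, key=lambda lab: (nearest[lab], lab))


def knn_predict(train: LabeledDataset, query, k: int, spec: DistanceSpec) -> str:
    """Plurality vote among the k nearest neighbours (minority follows majority)."""
    nb = neighborhood(train, query, k, spec)
    return _vote(nb.labels, nb.distances)


def predict_batch(train: LabeledDataset, Q: np.ndarray, k: int,
                  spec: DistanceSpec) -> np.ndarray:
    """Vectorized :func:`knn_predict` over the rows of Q."""
    if not 1 <= k <= train.n_samples:
        raise ValueError(f"k={k} out of range [1, {train.n_samples}]")
    dists = pairwise_distances(train.matrix, np.asarray(Q, dtype=float), spec)
    preds = np.empty(dists.shape[0], dtype=object)
    for i in range(dists.shape[0]):
        order = _sorted_order(dists[i])[:k]
        preds[i] = _vote(train.labels[order], dists[i][order])
    return preds


def evaluate_knn(train: LabeledDataset, test: LabeledDataset, k: int,
                 spec: DistanceSpec) -> float:
    """Test-set accuracy of the KNN classifier."""
    preds = predict_batch(train, test.matrix, k, spec)
    return classification_accuracy(test.labels, preds)


def misclassification_rate(nb: Neighborhood, predicted: str) -> float:
    """Fraction of neighbourhood labels differing from the prediction.

    Complements the agreement fraction exactly: rate + agreement == 1.
    """
    if nb.k == 0:
        raise ValueError("empty neighbourhood")
    return float(np.mean(nb.labels != predicted))


def scan_k(train: LabeledDataset, validation: LabeledDataset,
           k_values=None, spec: DistanceSpec | None = None
           ) -> list[tuple[int, float]]:
    """Recognition rate (validation accuracy) at each k.

    The default grid is the odd values 1, 3, …, 15 (capped at the training
    size); odd k avoids binary vote ties.
    """
    spec = spec or DistanceSpec()
    if k_values is None:
        k_values = [k for k in DEFAULT_K_GRID if k <= train.n_samples]
    k_values = list(k_values)
    if not k_values:
        raise ValueError("k_values must be nonempty")
    for k in k_values:
        if not 1 <= k <= train.n_samples:
            raise ValueError(f"k={k} out of range [1, {train.n_samples}]")
    dists = pairwise_distances(train.matrix, validation.matrix, spec)
    orders = [_sorted_order(dists[i]) for i in range(dists.shape[0])]
    result = []
    for k in k_values:
        preds = np.empty(dists.shape[0], dtype=object)
        for i, order in enumerate(orders):
            top = order[:k]
            preds[i] = _vote(train.labels[top], dists[i][top])
        result.append((k, classification_accuracy(validation.labels, preds)))
    return result
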