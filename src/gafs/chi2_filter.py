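"""Chi-square relevance filtering.

Features are scored by the chi-square statistic of their discretized levels
against the class labels: the larger the statistic, the stronger the
association.  Two forms are implemented from first principles:

* the general goodness-of-fit form  x² = Σ_i (f_i − n·p_i)² / (n·p_i), and
* the 2×2 shortcut  x² = n(ad−bc)² / [(a+c)(b+d)(a+b)(c+d)]  with df = 1,

which agree exactly on any 2×2 independence table when the expected
proportions come from the marginals.  No continuity correction is applied by
default (a Yates-corrected variant is exposed for comparison); p-values come
from the chi-square survival function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import LabeledDataset

__all__ = [
    "ContingencyTable",
    "Chi2Result",
    "RankedFeature",
    "chi2_general",
    "chi2_2x2",
    "chi2_independence",
    "rank_features",
    "select",
    "median_binarizer",
    "quantile_binarizer",
]


@dataclass
class ContingencyTable:
    """Observed r×c counts: rows = feature levels, columns = classes."""

    observed: np.ndarray

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed)
        if self.observed.ndim != 2 or min(self.observed.shape) < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(self.observed < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.observed.sum())


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_value: float


@dataclass
class RankedFeature:
    index: int
    name: str
    statistic: float
    df: int
    p_value: float


def chi2_general(observed, expected_probs) -> float:
    """Goodness-of-fit statistic Σ (f_i − n·p_i)² / (n·p_i)."""
    f = np.asarray(observed, dtype=float)
    p = np.asarray(expected_probs, dtype=float)
    if f.shape != p.shape or f.ndim != 1:
        raise ValueError("observed and expected_probs must be 1-D of equal length")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("expected probabilities must sum to 1")
    n = f.sum()
    e = n * p
    if np.any(e <= 0):
        raise ValueError("zero expected cell")
    return float(np.sum((f - e) ** 2 / e))


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> Chi2Result:
    """Independence statistic for the 2×2 table [[a, b], [c, d]], df = 1.

    ``yates`` subtracts the n/2 continuity correction from |ad−bc| before
    squaring; off by default.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("counts must be non-negative")
    n = cells.sum()
    marg = np.array([a + c, b + d, a + b, c + d], dtype=float)
    if np.any(marg == 0):
        raise ValueError("degenerate table: zero marginal")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    statistic = n * num ** 2 / marg.prod()
    return Chi2Result(float(statistic), 1, float(stats.chi2.sf(statistic, 1)))


def chi2_independence(table: ContingencyTable) -> Chi2Result:
    """General r×c independence statistic with df = (r−1)(c−1)."""
    obs = np.asarray(table.observed, dtype=float)
    n = obs.sum()
    if n == 0:
        raise ValueError("empty table")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n
    if np.any(expected == 0):
        raise ValueError("degenerate table: zero marginal")
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return Chi2Result(statistic, df, float(stats.chi2.sf(statistic, df)))


# ---------------------------------------------------------------------------
# Discretizers
# ---------------------------------------------------------------------------

def median_binarizer(values: np.ndarray) -> np.ndarray:
    """Above/below-median split: 1 ("Exist") if value > median, else 0 ("Absent")."""
    return (values > np.median(values)).astype(int)


def quantile_binarizer(n_bins: int):
    """Equal-frequency binning into ``n_bins`` levels (r > 2 uses df (r−1)(c−1))."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    def _bin(values: np.ndarray) -> np.ndarray:
        qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(qs, values, side="left")

    return _bin


# ---------------------------------------------------------------------------
# Ranking and selection
# ---------------------------------------------------------------------------

def rank_features(ds: LabeledDataset, binarizer=None) -> list[RankedFeature]:
    """Score every feature against the labels and sort descending by statistic.

    Each feature is discretized (default: median split), cross-tabulated
    against the classes and scored with the independence chi-square.  A
    feature that is constant after discretization gets statistic 0 (warned).
    Ties keep feature order (stable sort).
    """
    if ds.has_missing:
        raise ValueError("rank_features requires a complete matrix; impute first")
    ds.require_classification()
    binarizer = binarizer or median_binarizer
    classes = ds.classes
    y = np.searchsorted(np.array(classes, dtype=object), ds.labels)
    n_classes = len(classes)

    results: list[RankedFeature] = []
    for j in range(ds.n_features):
        levels = np.asarray(binarizer(ds.matrix[:, j]))
        uniq = np.unique(levels)
        if len(uniq) < 2:
            warnings.warn(
                f"feature {ds.feature_names[j]!r} is constant after discretization; "
                "statistic set to 0",
                stacklevel=2,
            )
            results.append(RankedFeature(j, ds.feature_names[j], 0.0,
                                         max(n_classes - 1, 1), 1.0))
            continue
        r = len(uniq)
        obs = np.zeros((r, n_classes))
        for li, lv in enumerate(uniq):
            sel = levels == lv
            obs[li] = np.bincount(y[sel], minlength=n_classes)
        res = chi2_independence(ContingencyTable(obs))
        results.append(RankedFeature(j, ds.feature_names[j],
                                     res.statistic, res.df, res.p_value))
    return sorted(results, key=lambda r: -r.statistic)


def select(ranked: list[RankedFeature], top_m: int | None = None,
           alpha: float | None = None) -> set[int]:
    """Top-m prefix of the ranking, or all features with p < alpha."""
    if (top_m is None) == (alpha is None):
        raise ValueError("give exactly one of top_m / alpha")
    if top_m is not None:
        if top_m > len(ranked):
            raise ValueError(f"top_m={top_m} exceeds feature count {len(ranked)}")
        return {r.index for r in ranked[:top_m]}
    if alpha >= 1.0:  # p-values of null features sit exactly at 1.0
        return {r.index for r in ranked}
    return {r.index for r in ranked if r.p_value < alpha}


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing correction, off by default)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * m / (rank + 1))
        adj[idx] = running
    return adj
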