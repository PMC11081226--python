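"""KNN missing-value imputation with co-observation masking.

Works on standardized data.  The distance between two incomplete rows is the
mean absolute difference over their co-observed coordinates (a masked taxicab
distance):

    d(x*_i, x*_j) = sum_n Z_in Z_jn |x*_in - x*_jn| / sum_n Z_in Z_jn,

undefined (NaN sentinel) when no coordinate is co-observed.  Each missing
standardized entry is estimated as an inverse-distance-weighted average over
the k-adjacent donor set, then mapped back to the original scale through the
stored per-feature affine parameters (x = x*·sigma + mu).

The weight function beta_ij = (1/(d_ij+eps)) / sum_j' (1/(d_ij'+eps)) with
eps = 1e-8 is this package's choice of the distance-related weighting; it is
normalized, non-negative, and monotone decreasing in distance.
"""

from __future__ import annotations

import numpy as np

from .data import LabeledDataset, destandardize, standardize

__all__ = [
    "masked_taxicab_distance",
    "neighbor_weights",
    "impute",
]

_EPS = 1e-8


def masked_taxicab_distance(xi, xj, zi=None, zj=None) -> float:
    """Mean |difference| over co-observed coordinates; NaN if none co-observed.

    Masks default to the non-NaN pattern of the rows themselves.
    """
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.ndim != 1:
        raise ValueError("rows must be 1-D of the same length")
    zi = ~np.isnan(xi) if zi is None else np.asarray(zi, dtype=bool)
    zj = ~np.isnan(xj) if zj is None else np.asarray(zj, dtype=bool)
    if zi.shape != xi.shape or zj.shape != xj.shape:
        raise ValueError("mask length mismatch")
    co = zi & zj
    n_co = int(co.sum())
    if n_co == 0:
        return float("nan")
    return float(np.abs(xi[co] - xj[co]).sum() / n_co)


def neighbor_weights(distances) -> np.ndarray:
    """Normalized inverse-distance weights beta over a donor set.

    beta_j = (1/(d_j+eps)) / sum(1/(d+eps)); non-negative, sums to one,
    smaller distance => larger weight.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance list")
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    inv = 1.0 / (d + _EPS)
    return inv / inv.sum()


def _masked_distances_to_all(X: np.ndarray, Z: np.ndarray, i: int) -> np.ndarray:
    """Masked taxicab distance from row i to every row (self -> NaN)."""
    co = Z & Z[i]
    diff = np.abs(X - X[i])
    diff[~co] = 0.0
    cnt = co.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(cnt > 0, diff.sum(axis=1) / np.maximum(cnt, 1), np.nan)
    d[i] = np.nan
    return d


def impute(ds: LabeledDataset, k: int = 7) -> LabeledDataset:
    """Fill every missing entry by masked-distance KNN estimation.

    Pipeline: standardize -> for each incomplete row, rank donor rows by the
    masked taxicab distance (undefined distances rank last), take the
    k-adjacent set, estimate each missing standardized value as the
    beta-weighted average over neighbours observing that feature
    (beta re-normalized over them; nearest eligible donor outside the set as
    fallback), then de-standardize.  Observed entries are returned bit-identical.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not ds.has_missing:
        return ds.copy()

    std_ds, params = standardize(ds)  # errors on an all-missing feature
    X = std_ds.matrix
    Z = ~np.isnan(X)
    if not Z.any(axis=1).all():
        i = int(np.flatnonzero(~Z.any(axis=1))[0])
        raise ValueError(f"sample {ds.sample_ids[i]!r} has no observed entries")

    filled = X.copy()
    for i in np.flatnonzero(~Z.all(axis=1)):
        d = _masked_distances_to_all(X, Z, i)
        defined = np.isfinite(d)
        if not defined.any():
            raise ValueError(
                f"sample {ds.sample_ids[i]!r} co-observes nothing with any other row"
            )
        # stable order, NaN-after-defined; theta capped at the defined count
        order = np.argsort(np.where(defined, d, np.inf), kind="stable")
        order = order[order != i]
        n_theta = min(k, int(defined.sum()))
        theta = order[:n_theta]
        beta = neighbor_weights(d[theta])
        for n in np.flatnonzero(~Z[i]):
            eligible = Z[theta, n]
            if eligible.any():
                b = beta[eligible]
                filled[i, n] = float((b / b.sum()) @ X[theta[eligible], n])
            else:
                # nearest donor outside theta observing feature n
                rest = order[n_theta:]
                cand = rest[Z[rest, n]]
                if cand.size:
                    filled[i, n] = X[cand[0], n]
                else:
                    filled[i, n] = 0.0  # standardized feature mean
    out = std_ds.copy()
    out.matrix = filled
    out = destandardize(out, params)
    # observed entries bit-identical: copy them straight from the input
    observed = ~np.isnan(ds.matrix)
    out.matrix[observed] = ds.matrix[observed]
    return out
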