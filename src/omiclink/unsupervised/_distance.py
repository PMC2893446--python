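"""Pairwise distances between genes or samples.

Four metrics: euclidean, manhattan, and the correlation distances
``1 − r`` for Pearson and Spearman (range [0, 2]; 0 = perfectly
correlated, 2 = perfectly anti-correlated).  Missing entries are handled
pairwise-complete: a pair of items is compared over the coordinates both
observe, and euclidean/manhattan sums are rescaled by ``p / p_complete``
so distances stay on the full-dimension scale.  An item with zero variance
has no defined correlation; its distances are reported missing and logged,
never silently zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from ..datamodel import FeatureMatrix

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "manhattan", "pearson", "spearman")


@dataclass
class DistanceMatrix:
    """Symmetric item–item distance matrix with zero diagonal.

    Carries the metric it was computed with so downstream steps (ward
    linkage, MDS) can check their own preconditions.
    """

    values: np.ndarray
    item_ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.item_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match item count")

    @property
    def n(self) -> int:
        return len(self.item_ids)

    def condensed(self) -> np.ndarray:
        if np.isnan(self.values).any():
            raise ValueError(
                "distance matrix contains missing entries (zero-variance items?); "
                "drop the affected items before clustering")
        return squareform(self.values, checks=False)


def _extract(matrix, axis: str):
    if isinstance(matrix, FeatureMatrix):
        X, ids = matrix.values, matrix.row_ids if axis == "rows" else matrix.col_ids
        if axis == "columns":
            X = X.T
        elif axis != "rows":
            raise ValueError("axis must be 'rows' or 'columns'")
        return np.asarray(X, dtype=float), list(ids)
    X = np.asarray(matrix, dtype=float)
    if axis == "columns":
        X = X.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    return X, [str(i) for i in range(X.shape[0])]


def _masked_minkowski(X: np.ndarray, power: int) -> np.ndarray:
    """Pairwise-complete euclidean (power 2) / manhattan (power 1) with NaN."""
    n, p = X.shape
    D = np.zeros((n, n))
    obs = ~np.isnan(X)
    Xz = np.where(obs, X, 0.0)
    for i in range(n):
        both = obs[i] & obs
        diff = np.abs(Xz[i] - Xz) * both
        m = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = (diff ** power).sum(axis=1) * (p / m)
        s[m == 0] = np.nan
        D[i] = s ** (1.0 / power)
    return D


def pairwise_distance(matrix, metric: str = "euclidean", axis: str = "rows") -> DistanceMatrix:
    """Compute all pairwise distances along one axis of a data matrix.

    Parameters
    ----------
    matrix : FeatureMatrix or array-like
        Data; for ``axis="columns"`` the samples are the items.
    metric : {"euclidean", "manhattan", "pearson", "spearman"}
        Correlation distances are ``1 − r`` on pairwise-complete entries;
        Spearman uses fractional (average) ranks.
    axis : {"rows", "columns"}

    Returns
    -------
    DistanceMatrix
        Symmetric, zero diagonal.  Entries involving an item whose
        correlation is undefined (zero variance, or fewer than two complete
        pairs) are NaN, with a logged warning.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    X, ids = _extract(matrix, axis)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to compute pairwise distances")
    if metric in ("euclidean", "manhattan"):
        if np.isnan(X).any():
            D = _masked_minkowski(X, 2 if metric == "euclidean" else 1)
        else:
            D = squareform(pdist(X, "euclidean" if metric == "euclidean" else "cityblock"))
    else:
        # pandas .corr is pairwise-complete and uses average ranks for spearman
        corr = pd.DataFrame(X.T).corr(method=metric, min_periods=2).to_numpy()
        D = 1.0 - corr
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float round-off
    n_missing = int(np.isnan(D).sum() // 2)
    if n_missing:
        logger.warning(
            "pairwise_distance(%s): %d pair distance(s) undefined "
            "(zero variance or too few complete pairs)", metric, n_missing)
    return DistanceMatrix(D, ids, metric)
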