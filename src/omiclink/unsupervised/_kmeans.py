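"""k-means partitioning of matrix rows.

Thin, reproducible wrapper over scikit-learn's Lloyd k-means with
k-means++ (farthest-point-style) seeding: the best of ``restarts`` seeded
runs by within-cluster sum of squares is kept, deterministic given the
seed.  Rows with missing entries are imputed by their own row mean for
this operation only (logged); the stored matrix is never modified.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans as _SKKMeans

from ..datamodel import FeatureMatrix
from ._hierarchy import Partition, _canonical_labels

logger = logging.getLogger(__name__)


def _prepare(matrix, axis: str = "rows"):
    if isinstance(matrix, FeatureMatrix):
        X = matrix.values if axis == "rows" else matrix.values.T
        ids = matrix.row_ids if axis == "rows" else matrix.col_ids
    else:
        X = np.asarray(matrix, dtype=float)
        if axis == "columns":
            X = X.T
        ids = [str(i) for i in range(X.shape[0])]
    X = np.array(X, dtype=float)
    nan_rows = np.isnan(X).any(axis=1)
    if nan_rows.any():
        if np.isnan(X).all(axis=1).any():
            raise ValueError("cannot impute a row with no observed entries")
        means = np.nanmean(X, axis=1)
        ii, jj = np.where(np.isnan(X))
        X[ii, jj] = means[ii]
        logger.warning("kmeans: imputed missing entries in %d row(s) by row mean",
                       int(nan_rows.sum()))
    return X, list(ids)


class KMeansClustering(ClusterMixin, BaseEstimator):
    """k-means over matrix rows with seeded restarts.

    Attributes (after ``fit``): ``labels_`` (0-based), ``partition_``
    (labels 1..k), ``cluster_centers_``, ``inertia_`` (within-cluster sum
    of squares of the best restart).
    """

    def __init__(self, n_clusters: int = 2, random_state: int = 0, restarts: int = 10):
        self.n_clusters = n_clusters
        self.random_state = random_state
        self.restarts = restarts

    def fit(self, X, y=None):
        X, ids = _prepare(X)
        if self.n_clusters > X.shape[0]:
            raise ValueError(
                f"k={self.n_clusters} exceeds the {X.shape[0]} available items")
        km = _SKKMeans(
            n_clusters=self.n_clusters,
            init="k-means++",
            n_init=self.restarts,
            random_state=self.random_state,
            algorithm="lloyd",
        ).fit(X)
        labels = _canonical_labels(km.labels_)
        self.partition_ = Partition(ids, labels, self.n_clusters)
        self.labels_ = labels - 1
        # reorder centers to match canonical 1..k labelling
        order = []
        seen = set()
        for raw in km.labels_:
            if raw not in seen:
                seen.add(raw)
                order.append(raw)
        self.cluster_centers_ = km.cluster_centers_[order]
        self.inertia_ = float(km.inertia_)
        return self


def kmeans(matrix, k: int, seed: int = 0, restarts: int = 10):
    """Partition matrix rows into ``k`` clusters.

    Returns ``(partition, centers, within_ss)`` — the best of ``restarts``
    seeded runs by within-cluster sum of squares.
    """
    est = KMeansClustering(n_clusters=k, random_state=seed, restarts=restarts).fit(matrix)
    return est.partition_, est.cluster_centers_, est.inertia_
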