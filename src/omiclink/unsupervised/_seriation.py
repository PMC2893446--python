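"""Seriation: linear orderings of genes or samples.

Three methods, all classical combinatorial-data-analysis orderings:

``pca``
    sort items by their score on the first principal component of the
    (column-centred) data matrix.
``mds``
    sort by the first dimension of classical metric scaling (Torgerson
    double-centring + leading eigenvector) of a distance matrix.
``leaf_order``
    the optimal leaf order of a dendrogram — the tree-consistent
    permutation minimizing the sum of distances between adjacent leaves,
    found by the exact dynamic program.

The direction of a pca/mds axis is arbitrary (an ordering and its reverse
are equivalent seriations); within a run the sign is fixed
deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ..datamodel import FeatureMatrix
from ._distance import DistanceMatrix, pairwise_distance
from ._hierarchy import Dendrogram, hierarchical_cluster
from ._olo import optimal_leaf_order

logger = logging.getLogger(__name__)

METHODS = ("pca", "mds", "leaf_order")


@dataclass
class Seriation:
    """A permutation of one axis of the data matrix."""

    axis: str  # "rows" | "columns"
    permutation: np.ndarray
    method: str
    item_ids: list[str] | None = None

    def __post_init__(self) -> None:
        perm = np.asarray(self.permutation, dtype=int)
        if sorted(perm.tolist()) != list(range(len(perm))):
            raise ValueError("permutation is not a bijection on the axis index set")
        self.permutation = perm

    def ordered_ids(self) -> list[str]:
        if self.item_ids is None:
            raise ValueError("no item identifiers attached")
        return [self.item_ids[i] for i in self.permutation]


def _first_component_scores(X: np.ndarray) -> np.ndarray | None:
    """Scores on the first PC of the column-centred matrix; None if degenerate."""
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(np.abs(Xc) > 1e-12):
        return None
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, 0] * s[0]
    # deterministic sign: largest-|loading| coordinate of the axis positive
    lead = np.argmax(np.abs(Vt[0]))
    if Vt[0][lead] < 0:
        scores = -scores
    return scores


def _classical_mds_scores(D: np.ndarray) -> np.ndarray | None:
    """First coordinate of Torgerson classical scaling; None if degenerate."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh((B + B.T) / 2)
    if w[-1] <= 1e-12:
        return None
    scores = v[:, -1] * np.sqrt(w[-1])
    lead = np.argmax(np.abs(scores))
    if scores[lead] < 0:
        scores = -scores
    return scores


def seriate(data=None, distances: DistanceMatrix | None = None,
            dendrogram: Dendrogram | None = None,
            method: str = "pca", axis: str = "rows") -> Seriation:
    """Order the items on one axis.

    ``pca`` needs the data matrix; ``mds`` a distance matrix;
    ``leaf_order`` a dendrogram plus the distance matrix it was built from.
    A degenerate input (all items identical) yields the identity
    permutation with a logged note.
    """
    if method not in METHODS:
        raise ValueError(f"unknown seriation method {method!r}")
    ids: list[str] | None = None
    if method == "pca":
        if data is None:
            raise ValueError("pca seriation requires the data matrix")
        if isinstance(data, FeatureMatrix):
            X = data.values if axis == "rows" else data.values.T
            ids = data.row_ids if axis == "rows" else data.col_ids
        else:
            X = np.asarray(data, dtype=float)
            if axis == "columns":
                X = X.T
        if np.isnan(X).any():
            X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
        scores = _first_component_scores(X)
        if scores is None:
            logger.warning("seriate(pca): degenerate input, identity order returned")
            perm = np.arange(X.shape[0])
        else:
            perm = np.argsort(scores, kind="stable")
    elif method == "mds":
        if distances is None:
            raise ValueError("mds seriation requires a distance matrix")
        ids = distances.item_ids
        scores = _classical_mds_scores(distances.values)
        if scores is None:
            logger.warning("seriate(mds): degenerate input, identity order returned")
            perm = np.arange(distances.n)
        else:
            perm = np.argsort(scores, kind="stable")
    else:  # leaf_order
        if dendrogram is None or distances is None:
            raise ValueError("leaf_order seriation requires a dendrogram and distances")
        ids = dendrogram.item_ids
        perm = optimal_leaf_order(dendrogram.Z, distances.values)
    return Seriation(axis, perm, method, list(ids) if ids is not None else None)


class SeriationTransformer(TransformerMixin, BaseEstimator):
    """Fit a row ordering and reorder matrices with it.

    For ``method="mds"`` and ``"leaf_order"`` the distance matrix (and,
    for the latter, an agglomerative dendrogram) are computed internally
    from ``metric`` / ``linkage``.

    Attributes: ``seriation_``, ``order_`` (the permutation).
    """

    def __init__(self, method: str = "pca", metric: str = "euclidean",
                 linkage: str = "average"):
        self.method = method
        self.metric = metric
        self.linkage = linkage

    def fit(self, X, y=None):
        if self.method == "pca":
            self.seriation_ = seriate(data=X, method="pca", axis="rows")
        else:
            D = pairwise_distance(X, self.metric, axis="rows")
            if self.method == "mds":
                self.seriation_ = seriate(distances=D, method="mds", axis="rows")
            else:
                dend = hierarchical_cluster(D, self.linkage)
                self.seriation_ = seriate(distances=D, dendrogram=dend,
                                          method="leaf_order", axis="rows")
        self.order_ = self.seriation_.permutation
        return self

    def transform(self, X):
        if isinstance(X, FeatureMatrix):
            return X.reorder(row_order=self.order_)
        return np.asarray(X)[self.order_]
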