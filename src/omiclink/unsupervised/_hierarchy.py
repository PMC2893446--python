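"""Agglomerative hierarchical clustering.

Agglomeration follows the Lance–Williams update rules via
:func:`scipy.cluster.hierarchy.linkage` on a precomputed distance matrix.
Four linkages: single, complete, average, ward — ward only on euclidean
distances, where its variance interpretation is valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as _sch
from sklearn.base import BaseEstimator, ClusterMixin

from ._distance import DistanceMatrix, pairwise_distance

LINKAGES = ("single", "complete", "average", "ward")


@dataclass
class Dendrogram:
    """Result of agglomerative clustering over ``n`` items.

    ``merges`` lists the ``n − 1`` agglomeration steps as
    ``(node_a, node_b, height)``; nodes ``0 .. n−1`` are leaves and node
    ``n + i`` is the cluster created by merge ``i``.  ``leaf_order`` is a
    tree-consistent permutation of the items (no branch crossings).
    """

    item_ids: list[str]
    Z: np.ndarray  # scipy linkage matrix, shape (n-1, 4)
    linkage: str
    metric: str
    leaf_order_override: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.item_ids)

    @property
    def merges(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(h)) for a, b, h, _ in self.Z]

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2].copy()

    @property
    def leaf_order(self) -> np.ndarray:
        if self.leaf_order_override is not None:
            return self.leaf_order_override
        return _sch.leaves_list(self.Z)

    def with_leaf_order(self, distances: DistanceMatrix) -> "Dendrogram":
        """Return a copy whose leaf order is the optimal one (see seriation)."""
        from ._olo import optimal_leaf_order

        order = optimal_leaf_order(self.Z, distances.values)
        return Dendrogram(self.item_ids, self.Z, self.linkage, self.metric,
                          leaf_order_override=order)


def hierarchical_cluster(distances: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerate a distance matrix into a dendrogram.

    Raises if ``linkage="ward"`` is requested on non-euclidean distances,
    or if the distance matrix has missing entries.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if linkage == "ward" and distances.metric != "euclidean":
        raise ValueError(
            f"ward linkage requires euclidean distances, got {distances.metric!r}")
    Z = _sch.linkage(distances.condensed(), method=linkage)
    return Dendrogram(distances.item_ids, Z, linkage, distances.metric)


@dataclass
class Partition:
    """Flat cluster assignment: labels take exactly the values ``1 .. k'``
    with ``k' ≤ k`` (relabelled by order of first appearance)."""

    item_ids: list[str]
    labels: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.item_ids):
            raise ValueError("labels length does not match item count")

    def members(self, label: int) -> list[str]:
        return [i for i, l in zip(self.item_ids, self.labels) if l == label]

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.item_ids, (int(l) for l in self.labels)))


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel to 1..k' by order of first appearance (deterministic)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, l in enumerate(raw):
        if l not in mapping:
            mapping[l] = len(mapping) + 1
        out[i] = mapping[l]
    return out


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> Partition:
    """Cut the ``k − 1`` highest merges to obtain ``k`` flat clusters."""
    n = dendrogram.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = _sch.cut_tree(dendrogram.Z, n_clusters=k).ravel()
    return Partition(dendrogram.item_ids, _canonical_labels(raw), k)


class HierarchicalClustering(ClusterMixin, BaseEstimator):
    """Agglomerative clustering of matrix rows, scikit-learn style.

    Parameters
    ----------
    n_clusters : int
        Number of flat clusters cut from the dendrogram.
    metric : {"euclidean", "manhattan", "pearson", "spearman", "precomputed"}
        Distance between rows; ``"precomputed"`` expects a
        :class:`DistanceMatrix` (or square array) in ``fit``.
    linkage : {"single", "complete", "average", "ward"}

    Attributes
    ----------
    dendrogram_ : Dendrogram
    distances_ : DistanceMatrix
    partition_ : Partition  (labels 1..k)
    labels_ : ndarray       (same partition, 0-based per sklearn convention)
    """

    def __init__(self, n_clusters: int = 2, metric: str = "euclidean",
                 linkage: str = "average"):
        self.n_clusters = n_clusters
        self.metric = metric
        self.linkage = linkage

    def fit(self, X, y=None):
        if self.metric == "precomputed":
            if isinstance(X, DistanceMatrix):
                self.distances_ = X
            else:
                X = np.asarray(X, dtype=float)
                self.distances_ = DistanceMatrix(
                    X, [str(i) for i in range(X.shape[0])], "euclidean")
        else:
            self.distances_ = pairwise_distance(X, self.metric, axis="rows")
        self.dendrogram_ = hierarchical_cluster(self.distances_, self.linkage)
        self.partition_ = cut_dendrogram(self.dendrogram_, self.n_clusters)
        self.labels_ = self.partition_.labels - 1
        return self
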