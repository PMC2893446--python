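"""Cluster-agreement analysis.

Two clusterings of the same objects — or a clustering against a
categorical clinical variable — are compared through their confusion
matrix.  A sorting step permutes rows and columns so that agreeing
clusters line up on the diagonal; the permutations maximize the diagonal
sum exactly, via optimal assignment on the count matrix (after padding a
rectangular matrix square with zeros).  The adjusted Rand index gives the
matching chance-corrected agreement number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

__all__ = ["ConfusionMatrix", "confusion_matrix", "sort_confusion", "adjusted_rand"]


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of two labelings of the same items.

    ``counts[i, j]`` is the number of items in cluster ``row_labels[i]``
    of labeling A and class ``col_labels[j]`` of labeling B; the counts
    sum to the number of co-labeled items.  After :func:`sort_confusion`
    the optional permutations give the diagonal-maximizing display order.
    """

    counts: np.ndarray
    row_labels: list
    col_labels: list
    row_perm: np.ndarray | None = None
    col_perm: np.ndarray | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def sorted_counts(self) -> np.ndarray:
        if self.row_perm is None or self.col_perm is None:
            raise ValueError("call sort_confusion first")
        return self.counts[np.ix_(self.row_perm, self.col_perm)]


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v))


def confusion_matrix(labels_a: Mapping, labels_b: Mapping) -> ConfusionMatrix:
    """Cross-tabulate two labelings given as ``item -> label`` mappings.

    Items missing a label in either input are dropped with a logged count;
    completely disjoint item sets are an error.
    """
    common = [i for i in labels_a if i in labels_b
              and not _is_missing(labels_a[i]) and not _is_missing(labels_b[i])]
    dropped = len(set(labels_a) | set(labels_b)) - len(common)
    if not common:
        raise ValueError("labelings share no co-labeled items")
    if dropped:
        logger.warning("confusion_matrix: %d item(s) without both labels dropped", dropped)
    row_labels = sorted({labels_a[i] for i in common}, key=str)
    col_labels = sorted({labels_b[i] for i in common}, key=str)
    ri = {l: k for k, l in enumerate(row_labels)}
    ci = {l: k for k, l in enumerate(col_labels)}
    counts = np.zeros((len(row_labels), len(col_labels)), dtype=int)
    for i in common:
        counts[ri[labels_a[i]], ci[labels_b[i]]] += 1
    return ConfusionMatrix(counts, row_labels, col_labels, n_dropped=dropped)


def sort_confusion(counts) -> tuple[np.ndarray, np.ndarray]:
    """Row/column permutations maximizing the diagonal sum.

    The smaller dimension is padded with zero rows/columns, the optimum is
    found by optimal assignment, and the padding is dropped again, so the
    returned permutations act on the original shape.  Accepts a raw count
    matrix or a :class:`ConfusionMatrix` (which gets its ``row_perm`` /
    ``col_perm`` fields filled in).
    """
    cm = counts if isinstance(counts, ConfusionMatrix) else None
    C = (cm.counts if cm is not None else np.asarray(counts, dtype=int))
    if (C < 0).any():
        raise ValueError("counts must be non-negative")
    r, c = C.shape
    k = max(r, c)
    padded = np.zeros((k, k), dtype=int)
    padded[:r, :c] = C
    ri, ci = linear_sum_assignment(padded, maximize=True)
    sigma = dict(zip(ri.tolist(), ci.tolist()))
    # keep only real-row -> real-col matches; padding pairs carry zero count
    matched = [(i, sigma[i]) for i in range(r) if sigma[i] < c]
    row_perm = [i for i, _ in matched] + [i for i in range(r)
                                          if i not in {m[0] for m in matched}]
    col_perm = [j for _, j in matched] + [j for j in range(c)
                                          if j not in {m[1] for m in matched}]
    row_perm = np.array(row_perm, dtype=int)
    col_perm = np.array(col_perm, dtype=int)
    if cm is not None:
        cm.row_perm, cm.col_perm = row_perm, col_perm
    return row_perm, col_perm


def diagonal_sum(counts: np.ndarray, row_perm, col_perm) -> int:
    """Sum of diagonal entries after applying the permutations."""
    P = np.asarray(counts)[np.ix_(row_perm, col_perm)]
    return int(np.trace(P))


def adjusted_rand(labels_a: Mapping | Sequence, labels_b: Mapping | Sequence) -> float:
    """Adjusted-for-chance Rand index in [−1, 1].

    Accepts item → label mappings (compared over the shared items) or two
    equal-length label sequences.  1 for identical partitions, ≈0 for
    independent ones.
    """
    if isinstance(labels_a, Mapping) and isinstance(labels_b, Mapping):
        common = [i for i in labels_a if i in labels_b]
        a = [labels_a[i] for i in common]
        b = [labels_b[i] for i in common]
    else:
        a, b = list(labels_a), list(labels_b)
        if len(a) != len(b):
            raise ValueError("label sequences differ in length")
    if len(a) < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score([str(x) for x in a], [str(x) for x in b]))
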