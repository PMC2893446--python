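"""Biclustering: simultaneous clustering of genes and samples.

Two complementary algorithms:

* **Cheng–Church δ-biclustering** on real-valued expression.  A bicluster
  is a submatrix whose entries are close to an additive row-effect +
  column-effect model; coherence is the *mean squared residue*

      H(I, J) = mean over (i,j) of (a_ij − a_iJ − a_Ij + a_IJ)²

  with a_iJ the row means, a_Ij the column means and a_IJ the overall
  mean of the submatrix.  Starting from the full matrix, rows/columns are
  greedily deleted (multiple-node deletion at threshold α·H, then
  single-node deletion) until H ≤ δ, then nodes whose residue does not
  raise H are added back.  After each bicluster its cells are masked with
  seeded uniform noise over the data range so subsequent biclusters
  explore different structure.

* **Bimax** on binary (e.g. thresholded or gain/loss indicator) matrices:
  enumerates inclusion-maximal all-ones submatrices exactly, via the
  correspondence with formal concepts (maximal bipartite bicliques) of
  the row/column incidence relation.

Biclusters may overlap, and items may belong to no bicluster at all —
genes in several biclusters can be read as participating in several
processes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, BiclusterMixin

from ..datamodel import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Bicluster:
    """A subset of rows × subset of columns, with an optional coherence score
    (mean squared residue; ``None`` for binary biclusters)."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.row_ids or not self.col_ids:
            raise ValueError("bicluster row and column sets must be non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_ids), len(self.col_ids))

    def cells(self) -> set[tuple[str, str]]:
        return {(r, c) for r in self.row_ids for c in self.col_ids}


def _as_array(matrix) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(matrix, FeatureMatrix):
        return np.asarray(matrix.values, dtype=float), list(matrix.row_ids), list(matrix.col_ids)
    X = np.asarray(matrix, dtype=float)
    return (X, [str(i) for i in range(X.shape[0])], [str(j) for j in range(X.shape[1])])


def mean_squared_residue(matrix, rows: Sequence[int], cols: Sequence[int]) -> float:
    """Mean squared residue H(I, J) of a submatrix.

    ``rows``/``cols`` are integer indices into ``matrix``.  Zero for any
    constant or perfectly additive (row effect + column effect) block.
    Missing entries inside the submatrix are an error: the residue is not
    defined there.
    """
    X, _, _ = _as_array(matrix)
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("rows and cols must be non-empty")
    sub = X[np.ix_(rows, cols)]
    if np.isnan(sub).any():
        raise ValueError("submatrix contains missing entries; impute or drop first")
    resid = sub - sub.mean(1, keepdims=True) - sub.mean(0, keepdims=True) + sub.mean()
    return float((resid ** 2).mean())


def _residue_parts(A, rows, cols):
    sub = A[np.ix_(rows, cols)]
    resid = sub - sub.mean(1, keepdims=True) - sub.mean(0, keepdims=True) + sub.mean()
    sq = resid ** 2
    return float(sq.mean()), sq.mean(axis=1), sq.mean(axis=0)


class ChengChurch(BiclusterMixin, BaseEstimator):
    """Cheng–Church δ-biclustering of a real matrix.

    Parameters
    ----------
    delta : float ≥ 0
        Maximum allowed mean squared residue of a reported bicluster.
    alpha : float ≥ 1
        Multiple-node-deletion aggressiveness: rows/columns with mean
        residue above ``alpha · H`` are dropped together.
    n_biclusters : int
        Maximum number of biclusters to extract.
    random_state : int
        Seeds the uniform masking noise; the whole procedure is
        deterministic given this seed.

    Attributes
    ----------
    biclusters_list_ : list of (row_indices, col_indices, score)
    rows_, columns_ : boolean arrays (n_biclusters × n_rows / n_cols),
        the scikit-learn bicluster convention.
    """

    def __init__(self, delta: float = 0.1, alpha: float = 1.2,
                 n_biclusters: int = 10, random_state: int = 0):
        self.delta = delta
        self.alpha = alpha
        self.n_biclusters = n_biclusters
        self.random_state = random_state

    # -- the three phases ---------------------------------------------------
    def _multiple_deletion(self, A, rows, cols):
        while len(rows) > 1 and len(cols) > 1:
            H, dr, dc = _residue_parts(A, rows, cols)
            if H <= self.delta:
                return rows, cols
            keep_r = dr <= self.alpha * H
            changed = False
            if 0 < keep_r.sum() < len(rows):
                rows = rows[keep_r]
                changed = True
            if len(rows) > 1:
                H, dr, dc = _residue_parts(A, rows, cols)
                if H <= self.delta:
                    return rows, cols
                keep_c = dc <= self.alpha * H
                if 0 < keep_c.sum() < len(cols):
                    cols = cols[keep_c]
                    changed = True
            if not changed:
                break
        return rows, cols

    def _single_deletion(self, A, rows, cols):
        while len(rows) > 1 or len(cols) > 1:
            H, dr, dc = _residue_parts(A, rows, cols)
            if H <= self.delta:
                break
            worst_row = dr.max() if len(rows) > 1 else -np.inf
            worst_col = dc.max() if len(cols) > 1 else -np.inf
            if worst_row >= worst_col:
                rows = np.delete(rows, int(dr.argmax()))
            else:
                cols = np.delete(cols, int(dc.argmax()))
        return rows, cols

    def _addition(self, A, rows, cols):
        n, m = A.shape
        while True:
            H, _, _ = _residue_parts(A, rows, cols)
            grown = False
            # columns whose residue against the current block is ≤ H
            sub = A[np.ix_(rows, cols)]
            aiJ = sub.mean(1)
            aIJ = sub.mean()
            col_means = A[rows].mean(0)
            resid = A[rows] - aiJ[:, None] - col_means[None, :] + aIJ
            col_score = (resid ** 2).mean(0)
            cand = np.setdiff1d(np.arange(m), cols)
            add_c = cand[col_score[cand] <= H]
            if add_c.size:
                new_cols = np.sort(np.concatenate([cols, add_c]))
                if _residue_parts(A, rows, new_cols)[0] <= self.delta:
                    cols = new_cols
                    grown = True
                    H, _, _ = _residue_parts(A, rows, cols)
            # rows, symmetrically
            sub = A[np.ix_(rows, cols)]
            aIj = sub.mean(0)
            aIJ = sub.mean()
            row_means = A[:, cols].mean(1)
            resid = A[:, cols] - row_means[:, None] - aIj[None, :] + aIJ
            row_score = (resid ** 2).mean(1)
            cand = np.setdiff1d(np.arange(n), rows)
            add_r = cand[row_score[cand] <= H]
            if add_r.size:
                new_rows = np.sort(np.concatenate([rows, add_r]))
                if _residue_parts(A, new_rows, cols)[0] <= self.delta:
                    rows = new_rows
                    grown = True
            if not grown:
                return rows, cols

    def fit(self, X, y=None):
        A, row_ids, col_ids = _as_array(X)
        if not np.isfinite(A).all():
            raise ValueError("Cheng-Church requires finite data (no NaN/inf)")
        if self.delta < 0 or self.alpha < 1:
            raise ValueError("require delta >= 0 and alpha >= 1")
        A = A.copy()
        lo, hi = float(A.min()), float(A.max())
        rng = np.random.default_rng(self.random_state)
        n, m = A.shape
        found: list[tuple[np.ndarray, np.ndarray, float]] = []
        for _ in range(self.n_biclusters):
            rows = np.arange(n)
            cols = np.arange(m)
            rows, cols = self._multiple_deletion(A, rows, cols)
            rows, cols = self._single_deletion(A, rows, cols)
            rows, cols = self._addition(A, rows, cols)
            score = mean_squared_residue(A, rows, cols)
            if score > self.delta:  # cannot happen by construction; guard anyway
                break
            found.append((rows, cols, score))
            if len(rows) == n and len(cols) == m:
                break  # whole matrix is one bicluster; nothing left to mask
            A[np.ix_(rows, cols)] = rng.uniform(lo, hi, size=(len(rows), len(cols)))
        self._row_ids = row_ids
        self._col_ids = col_ids
        self.biclusters_list_ = found
        self.rows_ = np.zeros((len(found), n), dtype=bool)
        self.columns_ = np.zeros((len(found), m), dtype=bool)
        for i, (r, c, _) in enumerate(found):
            self.rows_[i, r] = True
            self.columns_[i, c] = True
        return self

    def to_biclusters(self) -> list[Bicluster]:
        return [
            Bicluster(tuple(self._row_ids[i] for i in r),
                      tuple(self._col_ids[j] for j in c), s)
            for r, c, s in self.biclusters_list_
        ]


def cc_biclusters(matrix, delta: float, alpha: float = 1.2,
                  max_biclusters: int = 10, seed: int = 0) -> list[Bicluster]:
    """Extract up to ``max_biclusters`` Cheng–Church δ-biclusters."""
    est = ChengChurch(delta=delta, alpha=alpha, n_biclusters=max_biclusters,
                      random_state=seed).fit(matrix)
    return est.to_biclusters()


# --------------------------------------------------------------------------
# Bimax

class Bimax(BiclusterMixin, BaseEstimator):
    """Exact enumeration of inclusion-maximal all-ones submatrices.

    Maximal all-ones submatrices of a binary matrix are exactly the formal
    concepts of its row/column incidence relation: pairs (R, C) with
    C = ∩_{r∈R} cols(r) and R = {rows ⊇ C}.  All concept intents are
    generated by closing the family of row column-sets under pairwise
    intersection (rows as bitmasks), then filtered by the size minima.
    Results are sorted by descending area, then lexicographic row set, so
    output order is deterministic.
    """

    #: safety valve for dense matrices whose concept lattice explodes
    MAX_INTENTS = 200_000

    def __init__(self, min_rows: int = 2, min_cols: int = 2, max_biclusters: int = 100):
        self.min_rows = min_rows
        self.min_cols = min_cols
        self.max_biclusters = max_biclusters

    def fit(self, X, y=None):
        B, row_ids, col_ids = _as_array(X)
        if not np.isin(B[~np.isnan(B)], (0.0, 1.0)).all() or np.isnan(B).any():
            raise ValueError("Bimax requires a binary 0/1 matrix")
        B = B.astype(int)
        n, m = B.shape
        row_masks = [int("".join("1" if v else "0" for v in row[::-1]), 2) if row.any() else 0
                     for row in B.astype(bool)]
        base = sorted({rm for rm in row_masks if rm})
        intents = set(base)
        frontier = list(base)
        while frontier:
            new = []
            for a in frontier:
                for b in base:
                    c = a & b
                    if c and c not in intents:
                        intents.add(c)
                        new.append(c)
            if len(intents) > self.MAX_INTENTS:
                logger.warning("Bimax: concept lattice truncated at %d intents",
                               self.MAX_INTENTS)
                frontier = []
                break
            frontier = new
        found = []
        for intent in intents:
            if bin(intent).count("1") < self.min_cols:
                continue
            extent = [r for r in range(n) if row_masks[r] & intent == intent]
            if len(extent) < self.min_rows:
                continue
            # concept check: intent must be the exact intersection of its extent
            inter = extent and ~0
            for r in extent:
                inter &= row_masks[r]
            if inter != intent:
                continue  # not closed -> not maximal
            cols = [j for j in range(m) if intent >> j & 1]
            found.append((tuple(extent), tuple(cols)))
        found.sort(key=lambda rc: (-len(rc[0]) * len(rc[1]), rc[0], rc[1]))
        found = found[: self.max_biclusters]
        self._row_ids = row_ids
        self._col_ids = col_ids
        self.biclusters_list_ = [(np.array(r), np.array(c), None) for r, c in found]
        self.rows_ = np.zeros((len(found), n), dtype=bool)
        self.columns_ = np.zeros((len(found), m), dtype=bool)
        for i, (r, c) in enumerate(found):
            self.rows_[i, list(r)] = True
            self.columns_[i, list(c)] = True
        return self

    def to_biclusters(self) -> list[Bicluster]:
        return [
            Bicluster(tuple(self._row_ids[i] for i in r),
                      tuple(self._col_ids[j] for j in c), None)
            for r, c, _ in self.biclusters_list_
        ]


def bimax(matrix, min_rows: int = 2, min_cols: int = 2,
          max_results: int = 100) -> list[Bicluster]:
    """All inclusion-maximal all-ones submatrices meeting the size minima."""
    est = Bimax(min_rows=min_rows, min_cols=min_cols,
                max_biclusters=max_results).fit(matrix)
    return est.to_biclusters()
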