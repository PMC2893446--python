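"""Exact optimal leaf ordering of a dendrogram.

Among the 2^(n−1) leaf orders consistent with a binary merge tree (each
internal node may flip its two subtrees), find the one minimizing the sum
of distances between adjacent leaves — the classical optimal-leaf-ordering
dynamic program.  For every subtree and every feasible (leftmost, rightmost)
leaf pair the minimal internal cost is tabulated bottom-up; the combine
step is a pair of min-plus products, so the whole computation is
O(n^3)-ish on a balanced tree and exact always.
"""

from __future__ import annotations

import numpy as np

__all__ = ["optimal_leaf_order"]


def optimal_leaf_order(Z: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Optimal leaf order of linkage matrix ``Z`` under distance matrix ``D``.

    Returns the permutation of ``0..n−1`` (left to right) minimizing the
    sum of ``D`` over adjacent leaves among all tree-consistent orders.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n == 1:
        return np.array([0])
    leaves: dict[int, list[int]] = {v: [v] for v in range(n)}
    cost: dict[int, np.ndarray] = {v: np.zeros((1, 1)) for v in range(n)}

    def combine(A: int, B: int):
        """cost[l in A, r in B] for the A-block-left / B-block-right layout."""
        la, lb = leaves[A], leaves[B]
        Dab = D[np.ix_(la, lb)]
        # T[l, k] = min_m cost_A[l, m] + D[m, k]
        T = (cost[A][:, :, None] + Dab[None, :, :]).min(axis=1)
        # C[l, r] = min_k T[l, k] + cost_B[k, r]
        return (T[:, :, None] + cost[B][None, :, :]).min(axis=1)

    for i in range(Z.shape[0]):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        v = n + i
        la, lb = leaves[a], leaves[b]
        na, nb = len(la), len(lb)
        M = np.full((na + nb, na + nb), np.inf)
        M[:na, na:] = combine(a, b)
        M[na:, :na] = combine(b, a)
        leaves[v] = la + lb
        cost[v] = M

    def reconstruct(v: int, li: int, ri: int) -> list[int]:
        """Leaf sequence of subtree v with local endpoint indices (li, ri)."""
        if v < n:
            return [leaves[v][0]]
        a, b = int(Z[v - n, 0]), int(Z[v - n, 1])
        na = len(leaves[a])
        if li < na:  # a-block on the left
            A, B, loc_l, loc_r = a, b, li, ri - na
        else:
            A, B, loc_l, loc_r = b, a, li - na, ri
        la, lb = leaves[A], leaves[B]
        Dab = D[np.ix_(la, lb)]
        # re-derive the argmins of the combine step for this endpoint pair
        T_row = (cost[A][loc_l][:, None] + Dab).min(axis=0)
        k = int(np.argmin(T_row + cost[B][:, loc_r]))
        m = int(np.argmin(cost[A][loc_l] + Dab[:, k]))
        return reconstruct(A, loc_l, m) + reconstruct(B, k, loc_r)

    root = 2 * n - 2
    li, ri = np.unravel_index(int(np.argmin(cost[root])), cost[root].shape)
    order = reconstruct(root, int(li), int(ri))
    assert sorted(order) == list(range(n))
    return np.array(order)
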