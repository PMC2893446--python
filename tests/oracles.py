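"""Independent brute-force oracles the tests compare the package against.

Everything here is deliberately naive — O(n^3) agglomeration recomputing
all inter-cluster distances from scratch, exhaustive enumerations over
subsets and permutations — so that agreement with the package is
meaningful evidence, not self-confirmation.
"""

from itertools import permutations

import numpy as np


def naive_agglomerate(D: np.ndarray, linkage: str, points: np.ndarray | None = None):
    """O(n^3) agglomeration: at each step recompute every inter-cluster
    distance from the original pairwise matrix (or, for ward, from the
    points via the centroid formula) and merge the closest pair
    (ties: lowest pair index).

    Returns a list of (merged_leaf_set, height) per step.
    """
    n = D.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    steps = []

    def dist(A, B):
        if linkage == "single":
            return min(D[i, j] for i in A for j in B)
        if linkage == "complete":
            return max(D[i, j] for i in A for j in B)
        if linkage == "average":
            return float(np.mean([D[i, j] for i in A for j in B]))
        if linkage == "ward":
            ca = points[list(A)].mean(axis=0)
            cb = points[list(B)].mean(axis=0)
            return float(np.sqrt(2 * len(A) * len(B) / (len(A) + len(B)))
                         * np.linalg.norm(ca - cb))
        raise ValueError(linkage)

    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = dist(clusters[a], clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        steps.append((merged, d))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return steps


def mst_edge_weights(D: np.ndarray) -> np.ndarray:
    """Prim's algorithm by hand; returns sorted MST edge weights."""
    n = D.shape[0]
    in_tree = [0]
    out = set(range(1, n))
    weights = []
    best = {j: D[0, j] for j in out}
    while out:
        j = min(out, key=lambda x: (best[x], x))
        weights.append(best[j])
        out.remove(j)
        in_tree.append(j)
        for k in out:
            if D[j, k] < best[k]:
                best[k] = D[j, k]
    return np.sort(np.array(weights))


def tree_orders(Z: np.ndarray, n: int):
    """All 2^(n-1) tree-consistent leaf orders of a scipy linkage matrix."""

    def orders(node):
        if node < n:
            return [(node,)]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        out = []
        for oa in orders(a):
            for ob in orders(b):
                out.append(oa + ob)
                out.append(ob + oa)
        return out

    return orders(2 * n - 2)


def adjacent_distance_sum(order, D: np.ndarray) -> float:
    return float(sum(D[order[i], order[i + 1]] for i in range(len(order) - 1)))


def brute_maximal_all_ones(B: np.ndarray, min_rows: int, min_cols: int):
    """All inclusion-maximal all-ones submatrices by exhaustive search over
    row subsets (feasible to 8x8)."""
    n, m = B.shape
    found = set()
    for mask in range(1, 1 << n):
        R = [i for i in range(n) if mask >> i & 1]
        C = [j for j in range(m) if all(B[i, j] for i in R)]
        if not C:
            continue
        full_R = [i for i in range(n) if all(B[i, j] for j in C)]
        if full_R != R:
            continue  # not row-maximal for this column set
        if len(R) >= min_rows and len(C) >= min_cols:
            found.add((tuple(R), tuple(C)))
    return found


def brute_best_diagonal(C: np.ndarray) -> int:
    """Max diagonal sum over all row and column permutation pairs."""
    r, c = C.shape
    best = 0
    for rp in permutations(range(r)):
        for cp in permutations(range(c)):
            s = sum(C[rp[i], cp[i]] for i in range(min(r, c)))
            best = max(best, s)
    return int(best)


def pair_counting_ari(a, b) -> float:
    """Adjusted Rand index by explicit enumeration of all item pairs."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                ss += 1
            elif same_a:
                sd += 1
            elif same_b:
                ds += 1
            else:
                dd += 1
    num = 2.0 * (ss * dd - sd * ds)
    den = (ss + sd) * (sd + dd) + (ss + ds) * (ds + dd)
    return num / den if den else 1.0


def all_pairs_overlaps(markers, genes):
    """O(n*m) closed-interval overlap on the same chromosome."""
    pairs = set()
    for mk in markers:
        for g in genes:
            if (mk.chromosome == g.chromosome
                    and mk.start <= g.end and g.start <= mk.end):
                pairs.add((mk.id, g.id))
    return pairs
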