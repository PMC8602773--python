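"""Clustering and asymmetric open Hamiltonian-path search.

For each granularity k the cells are cut into k groups by hierarchical
clustering on the double-centered Spearman-distance representation, cluster
centroids are formed on the original log expression, and a minimum-cost open
path over the centroids is sought under the directed KL cost matrix with a
modified arbitrary-insertion heuristic.  A factorial brute-force solver is
provided as an exact oracle for small instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .distances import double_center, spearman_distance
from .preprocess import ExpressionMatrix

_LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterAssignment:
    """A k-group partition of cells with per-cluster centroid expression."""

    k: int
    labels: np.ndarray  # per-cell cluster index in [0, k)
    centroids: np.ndarray  # (k, n_genes) mean log expression per cluster

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        counts = np.bincount(self.labels, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every cluster must be non-empty")

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class HamiltonianPath:
    """An ordering of nodes and its total directed edge cost."""

    order: np.ndarray
    cost: float

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        if len(np.unique(self.order)) != len(self.order):
            raise ValueError("path must visit every node exactly once")

    def __len__(self) -> int:
        return len(self.order)

    def reversed(self) -> "HamiltonianPath":
        # cost is direction-dependent under asymmetric edges; caller must
        # recompute if needed
        return HamiltonianPath(self.order[::-1].copy(), np.nan)


def path_cost(order: np.ndarray, costs: np.ndarray) -> float:
    order = np.asarray(order, dtype=int)
    return float(costs[order[:-1], order[1:]].sum())


def linkage_tree(
    expr: ExpressionMatrix, method: str = "average"
) -> np.ndarray:
    """Linkage over cells on the double-centered Spearman representation.

    Computing the tree once lets every k in the consensus sweep reuse it.
    """
    if method not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}")
    d = spearman_distance(expr.values)
    b = double_center(d)
    return linkage(pdist(b), method=method)


def cluster_for_k(
    expr: ExpressionMatrix,
    k: int,
    method: str = "average",
    tree: np.ndarray | None = None,
    allow_small_k: bool = False,
) -> ClusterAssignment:
    """Cut the hierarchical tree at k groups and average member expression.

    Centroids are arithmetic means of member rows of the original (log)
    expression matrix, not of the centered representation.  Ties in the tree
    can make the cut return fewer than k distinct groups (e.g. duplicate
    cells); the assignment then has that smaller effective k.
    """
    n = expr.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    if k < 3 and not allow_small_k:
        raise ValueError("k < 3 is only allowed with allow_small_k=True")
    if tree is None:
        tree = linkage_tree(expr, method)
    raw = fcluster(tree, t=k, criterion="maxclust")
    uniq, labels = np.unique(raw, return_inverse=True)
    k_eff = len(uniq)
    centroids = np.empty((k_eff, expr.n_genes))
    for c in range(k_eff):
        centroids[c] = expr.values[labels == c].mean(axis=0)
    return ClusterAssignment(k=k_eff, labels=labels, centroids=centroids)


def _insert_all(order: list[int], v: int, costs: np.ndarray) -> int:
    """Return the position index minimizing the directed insertion cost.

    Position 0 prepends, position len(order) appends, position p in between
    inserts v between order[p-1] and order[p].
    """
    p = np.asarray(order, dtype=int)
    deltas = np.empty(len(order) + 1)
    deltas[0] = costs[v, p[0]]
    deltas[-1] = costs[p[-1], v]
    if len(order) > 1:
        deltas[1:-1] = costs[p[:-1], v] + costs[v, p[1:]] - costs[p[:-1], p[1:]]
    return int(np.argmin(deltas))


def insertion_path(
    costs: np.ndarray,
    restarts: int = 10,
    seed: int = 0,
    top_q: int = 10,
) -> HamiltonianPath:
    """Modified arbitrary insertion for an open path on asymmetric costs.

    Each restart seeds the path with a directed pair (a, b) drawn among the
    ``top_q`` largest off-diagonal costs (endpoint-spread seeding: nodes that
    are far apart in the directed cost tend to be good open-path endpoints),
    then inserts the remaining nodes in random order, each at the position
    minimizing the directed insertion cost — including prepending and
    appending, so both ends stay open.  The best of ``restarts`` runs is
    returned; ties are broken by lexicographic order so results are
    deterministic for a fixed seed.
    """
    costs = np.asarray(costs, dtype=float)
    n = costs.shape[0]
    if costs.ndim != 2 or costs.shape[1] != n or n < 2:
        raise ValueError("need a square cost matrix with n >= 2")
    if not np.all(np.isfinite(costs)):
        raise ValueError("cost matrix contains non-finite entries")
    if n == 2:
        order = [0, 1] if costs[0, 1] <= costs[1, 0] else [1, 0]
        return HamiltonianPath(np.array(order), path_cost(np.array(order), costs))

    off = costs.copy()
    np.fill_diagonal(off, -np.inf)
    q = min(top_q, n * (n - 1))
    flat = np.argsort(off, axis=None)[::-1][:q]
    seed_pairs = [divmod(int(f), n) for f in flat]

    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_order: tuple[int, ...] | None = None
    for _ in range(max(1, restarts)):
        a, b = seed_pairs[rng.integers(len(seed_pairs))]
        order = [a, b]
        remaining = [v for v in range(n) if v != a and v != b]
        rng.shuffle(remaining)
        for v in remaining:
            pos = _insert_all(order, v, costs)
            order.insert(pos, v)
        cost = path_cost(np.array(order), costs)
        key = tuple(order)
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and (best_order is None or key < best_order)
        ):
            best_cost = cost
            best_order = key
    assert best_order is not None
    return HamiltonianPath(np.array(best_order), best_cost)


def brute_force_path(costs: np.ndarray, max_n: int = 9) -> HamiltonianPath:
    """Exact minimum-cost open path by enumerating all n! orderings.

    Intended as a test oracle; refuses n > ``max_n``.  Ties are broken
    lexicographically.
    """
    costs = np.asarray(costs, dtype=float)
    n = costs.shape[0]
    if n > max_n:
        raise ValueError(f"brute force refuses n={n} > {max_n}")
    if n < 2:
        raise ValueError("need n >= 2")
    perms = np.array(list(permutations(range(n))), dtype=int)
    totals = costs[perms[:, :-1], perms[:, 1:]].sum(axis=1)
    best = np.flatnonzero(totals <= totals.min() + 1e-12)
    # permutations() yields lexicographic order, so the first hit wins ties
    order = perms[best[0]]
    return HamiltonianPath(order, float(totals[best[0]]))


def path_to_cell_scores(
    path: HamiltonianPath, assign: ClusterAssignment
) -> np.ndarray:
    """Project a cluster-level path onto per-cell scores in [0, 1].

    Every cell inherits the rank of its cluster along the path, min-max
    scaled; cells of the same cluster share a score.
    """
    k = assign.k
    if sorted(path.order.tolist()) != list(range(k)):
        raise ValueError("path does not cover exactly the clusters of the assignment")
    rank_of_cluster = np.empty(k)
    for rank, node in enumerate(path.order):
        rank_of_cluster[node] = rank
    if k == 1:
        return np.zeros(len(assign.labels))
    scores = rank_of_cluster[assign.labels] / (k - 1)
    return scores
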