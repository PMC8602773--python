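"""Consensus merging of per-k Hamiltonian paths into one pseudotime.

A path solved at granularity k yields per-cell scores in [0, 1], but each
solution's direction is arbitrary (a path read backwards is the same path).
The consensus procedure first builds a reference from the k = 3..7 score
vectors by exhaustively searching all 2^5 orientation assignments for the
one maximizing the sum of the C(5,2) pairwise Spearman correlations, then
streams the remaining k = 7..N vectors in, orienting each against the
current reference and folding it into a running average.  The same family
of path solutions is also accumulated into a cell-cell transition matrix
whose PCA embedding exposes linear versus branched topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.decomposition import PCA

from .distances import kl_cost_matrix
from .hampath import (
    ClusterAssignment,
    HamiltonianPath,
    cluster_for_k,
    insertion_path,
    linkage_tree,
    path_to_cell_scores,
)
from .preprocess import ExpressionMatrix


@dataclass
class PseudotimeVector:
    """Per-cell pseudotime scores in [0, 1].

    ``direction_anchor`` records how (or whether) the global direction was
    fixed; sorting the scores yields the consensus cell ordering.
    """

    scores: np.ndarray
    direction_anchor: str = "arbitrary"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.scores)

    def ordering(self) -> np.ndarray:
        return np.argsort(self.scores, kind="stable")

    def reflected(self) -> "PseudotimeVector":
        return PseudotimeVector(1.0 - self.scores, self.direction_anchor)


@dataclass
class ReferenceResult:
    """Reference pseudotime plus orientation-search diagnostics."""

    pseudotime: PseudotimeVector
    orientation: tuple[int, ...]
    best_score: float
    n_assignments_evaluated: int
    n_pairwise_scores: int


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi - lo <= 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _safe_spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return 0.0
    rho = spearmanr(a, b).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def build_reference_path(
    per_cell_scores: Sequence[np.ndarray | PseudotimeVector],
) -> ReferenceResult:
    """Merge the base per-k score vectors into one reference pseudotime.

    All ``2^m`` keep/reflect assignments of the m base vectors are
    enumerated; each is scored by the sum of the ``C(m,2)`` pairwise
    Spearman correlations of the oriented vectors, the argmax assignment is
    chosen, and the oriented vectors are averaged and min-max rescaled.
    A constant vector has undefined correlation and is treated as
    orientation-neutral (its pairwise terms contribute 0).
    """
    vecs = [
        v.scores if isinstance(v, PseudotimeVector) else np.asarray(v, dtype=float)
        for v in per_cell_scores
    ]
    m = len(vecs)
    if m < 2:
        raise ValueError("need at least 2 base score vectors")
    n = len(vecs[0])
    if any(len(v) != n for v in vecs):
        raise ValueError("base score vectors must have equal length")

    pairs = list(combinations(range(m), 2))
    rho = {(i, j): _safe_spearman(vecs[i], vecs[j]) for i, j in pairs}

    best_score = -np.inf
    best_signs: tuple[int, ...] = (1,) * m
    n_assignments = 0
    for signs in product((1, -1), repeat=m):
        n_assignments += 1
        # reflecting s -> 1-s negates the Spearman correlation, so each
        # pairwise term is signs[i]*signs[j]*rho without re-ranking
        score = sum(signs[i] * signs[j] * rho[(i, j)] for i, j in pairs)
        if score > best_score:
            best_score = score
            best_signs = signs
    oriented = [v if s == 1 else 1.0 - v for v, s in zip(vecs, best_signs)]
    merged = _minmax(np.mean(oriented, axis=0))
    return ReferenceResult(
        pseudotime=PseudotimeVector(merged, direction_anchor="arbitrary"),
        orientation=best_signs,
        best_score=float(best_score),
        n_assignments_evaluated=n_assignments,
        n_pairwise_scores=len(pairs),
    )


def merge_paths(
    reference: PseudotimeVector,
    later_scores: Iterable[np.ndarray | PseudotimeVector],
    reference_weight: int = 5,
) -> PseudotimeVector:
    """Fold further per-k score vectors into the reference pseudotime.

    Each incoming vector is kept or reflected to maximize its Spearman
    correlation with the current running mean, then merged with equal weight
    per contribution (the reference enters with weight ``reference_weight``,
    one unit per base vector it averaged).  The final result is min-max
    scaled to span exactly [0, 1].
    """
    mean = np.asarray(reference.scores, dtype=float).copy()
    count = float(max(1, reference_weight))
    for v in later_scores:
        s = v.scores if isinstance(v, PseudotimeVector) else np.asarray(v, dtype=float)
        if len(s) != len(mean):
            raise ValueError("score vector length mismatch")
        if _safe_spearman(s, mean) < _safe_spearman(1.0 - s, mean):
            s = 1.0 - s
        mean = (count * mean + s) / (count + 1.0)
        count += 1.0
    return PseudotimeVector(_minmax(mean), reference.direction_anchor)


@dataclass
class ConsensusResult:
    """Full output of the consensus pseudotime sweep."""

    pseudotime: PseudotimeVector
    reference: ReferenceResult
    per_k_scores: dict[int, np.ndarray]
    paths: list[HamiltonianPath] = field(default_factory=list)
    assignments: list[ClusterAssignment] = field(default_factory=list)


def consensus_pseudotime(
    expr: ExpressionMatrix,
    k_ref: tuple[int, int] = (3, 7),
    k_max: int | None = None,
    k_stride: int = 1,
    restarts: int = 10,
    seed: int = 0,
    linkage_method: str = "average",
    pseudocount: float = 1e-6,
    stage_labels: np.ndarray | None = None,
    root_cell: str | None = None,
) -> ConsensusResult:
    """Run the full consensus sweep: one path per k from ``k_ref[0]`` to N.

    For each k the cells are clustered, the directed KL cost matrix over the
    centroids is solved with the insertion heuristic, and the path is
    projected to per-cell scores.  Scores for k in ``k_ref`` build the
    reference; scores for k from ``k_ref[1]`` to N (k_max) are merged in.
    ``k_stride`` > 1 thins the merge stream for large N.

    If ``stage_labels`` (integer stages in known order) or ``root_cell`` is
    given, the global direction is fixed so the root/first stage sits at low
    pseudotime; otherwise the direction is arbitrary.
    """
    n = expr.n_cells
    k_lo, k_hi = k_ref
    if not (3 <= k_lo < k_hi):
        raise ValueError("k_ref must satisfy 3 <= lo < hi")
    k_max = n if k_max is None else min(k_max, n)
    if k_hi > k_max:
        raise ValueError(f"k_ref upper bound {k_hi} exceeds k_max={k_max}")

    tree = linkage_tree(expr, linkage_method)
    ks = list(range(k_lo, k_hi + 1)) + list(range(k_hi, k_max + 1, k_stride))
    if ks[-1] != k_max:
        ks.append(k_max)

    per_k_scores: dict[int, np.ndarray] = {}
    paths: list[HamiltonianPath] = []
    assignments: list[ClusterAssignment] = []
    for k in dict.fromkeys(ks):  # dedupe, preserve order
        assign = cluster_for_k(expr, k, method=linkage_method, tree=tree)
        if assign.k < 2:
            continue
        costs = kl_cost_matrix(assign.centroids, pseudocount=pseudocount)
        path = insertion_path(costs, restarts=restarts, seed=(seed * 1009 + k) % 2**31)
        per_k_scores[k] = path_to_cell_scores(path, assign)
        paths.append(path)
        assignments.append(assign)

    ref_ks = [k for k in range(k_lo, k_hi + 1) if k in per_k_scores]
    if len(ref_ks) < 2:
        raise ValueError("not enough reference paths; increase k_ref range")
    reference = build_reference_path([per_k_scores[k] for k in ref_ks])
    merge_ks = [k for k in per_k_scores if k >= k_hi]
    final = merge_paths(
        reference.pseudotime,
        [per_k_scores[k] for k in merge_ks],
        reference_weight=len(ref_ks),
    )

    anchor = "arbitrary"
    if root_cell is not None:
        idx = expr.cell_ids.index(root_cell)
        if final.scores[idx] > 0.5:
            final = PseudotimeVector(1.0 - final.scores)
        anchor = f"root cell {root_cell!r} at low pseudotime"
    elif stage_labels is not None:
        labels = np.asarray(stage_labels)
        lo_mean = final.scores[labels == labels.min()].mean()
        hi_mean = final.scores[labels == labels.max()].mean()
        if lo_mean > hi_mean:
            final = PseudotimeVector(1.0 - final.scores)
        anchor = "first stage at low pseudotime"
    final.direction_anchor = anchor
    return ConsensusResult(
        pseudotime=final,
        reference=reference,
        per_k_scores=per_k_scores,
        paths=paths,
        assignments=assignments,
    )


def transition_matrix(
    paths: Sequence[HamiltonianPath],
    assignments: Sequence[ClusterAssignment] | None = None,
    n_cells: int | None = None,
    symmetrize: bool = False,
    row_normalize: bool = False,
) -> np.ndarray:
    """Accumulate path transitions into an N x N mass matrix.

    Every consecutive node pair (u, v) of every path contributes unit mass
    to entry (u, v).  For cluster-level paths (``assignments`` given,
    parallel to ``paths``) the unit mass of an adjacent cluster pair is
    split uniformly over all member-cell pairs, so cluster sizes do not
    inflate the total: each path contributes exactly (len(path) - 1) mass.
    """
    if len(paths) == 0:
        raise ValueError("need at least one path")
    if assignments is not None:
        if len(assignments) != len(paths):
            raise ValueError("assignments must parallel paths")
        n = len(assignments[0].labels)
    else:
        if n_cells is None:
            n = max(int(p.order.max()) for p in paths) + 1
        else:
            n = n_cells
    t = np.zeros((n, n))
    for i, path in enumerate(paths):
        order = path.order
        if order.max() >= n and assignments is None:
            raise ValueError(f"path node {order.max()} outside matrix of size {n}")
        if assignments is None:
            t[order[:-1], order[1:]] += 1.0
        else:
            assign = assignments[i]
            for u, v in zip(order[:-1], order[1:]):
                mu = assign.members(int(u))
                mv = assign.members(int(v))
                t[np.ix_(mu, mv)] += 1.0 / (len(mu) * len(mv))
    np.fill_diagonal(t, 0.0)
    if symmetrize:
        t = t + t.T
    if row_normalize:
        sums = t.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(sums > 0, t / sums, 0.0)
    return t


def embed_transitions(
    t: np.ndarray,
    n_components: int = 2,
    symmetrize: bool = True,
    row_normalize: bool = False,
) -> np.ndarray:
    """PCA embedding of the transition-matrix rows.

    By default PCA is applied to rows of the symmetrized ``t + t'`` matrix.
    Component signs are fixed by making each component's largest-magnitude
    loading positive, so the embedding is deterministic.
    """
    t = np.asarray(t, dtype=float)
    n = t.shape[0]
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} cells")
    if not np.any(t):
        raise ValueError("no transitions recorded")
    m = t + t.T if symmetrize else t.copy()
    if row_normalize:
        sums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(sums > 0, m / sums, 0.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(m)
    for j in range(n_components):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def write_pseudotime(pt: PseudotimeVector, cell_ids: Sequence[str], path) -> None:
    import pandas as pd

    order = pt.ordering()
    rank = np.empty(len(pt), dtype=int)
    rank[order] = np.arange(len(pt))
    pd.DataFrame(
        {"cell_id": list(cell_ids), "score": pt.scores, "rank": rank}
    ).to_csv(path, sep="\t", index=False)
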