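"""Quiescent (G0) cell detection and cycle-differentiation coupling.

Cycling genes are largely silent in quiescent cells, so a cell whose mean
expression is lowest across all six cell-cycle phase score sets (G1, S,
G1/S, G2, M, G2/M; e.g. Cyclebase annotations) is a G0 candidate.  Cells
are k-means clustered (k = 5: G0, G1, S, G2, M) on the six scores, and the
cluster with the lowest grand mean is declared G0 only if it is
significantly lower than every other cluster on every score.  For coupling
plots, a cyclic cell-cycle pseudotime is wrapped onto the unit circle and
the differentiation pseudotime becomes the vertical axis of a 3-D spiral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .consensus import PseudotimeVector
from .preprocess import ExpressionMatrix, GeneSet

PHASE_NAMES = ("G1", "S", "G1/S", "G2", "M", "G2/M")


@dataclass
class G0Report:
    """Outcome of G0 detection.

    ``g0_cell_ids`` is the candidate cluster's membership iff every one of
    the 6 x (k-1) score-vs-cluster comparisons is significant at alpha;
    otherwise it is empty.  ``p_values`` has one row per phase score and one
    column per non-candidate cluster.
    """

    g0_cell_ids: list[str]
    candidate_cluster: int
    p_values: pd.DataFrame
    cluster_labels: np.ndarray
    alpha: float

    @property
    def significant(self) -> bool:
        return len(self.g0_cell_ids) > 0


def phase_scores(
    expr: ExpressionMatrix, phase_sets: dict[str, GeneSet]
) -> pd.DataFrame:
    """Per-cell mean log expression over each phase's genes.

    ``phase_sets`` maps the six phase names to gene sets; each score is the
    arithmetic mean over that phase's genes present in the matrix (set
    semantics: duplicates count once).
    """
    missing = [p for p in PHASE_NAMES if p not in phase_sets]
    if missing:
        raise ValueError(f"missing phase gene set(s): {missing}")
    cols = {}
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    for phase in PHASE_NAMES:
        idx = sorted(gene_index[g] for g in phase_sets[phase].genes if g in gene_index)
        if not idx:
            raise ValueError(f"phase {phase!r} has no genes in the expression matrix")
        cols[phase] = expr.values[:, idx].mean(axis=1)
    return pd.DataFrame(cols, index=expr.cell_ids, columns=list(PHASE_NAMES))


def detect_g0(
    scores: pd.DataFrame,
    alpha: float = 0.001,
    k: int = 5,
    seed: int = 0,
    pooled: bool = False,
    classic_anova: bool = False,
) -> G0Report:
    """Detect a quiescent cluster from the six phase scores.

    k-means (k = 5 by default) partitions cells on the score table; the
    candidate is the cluster with the lowest grand mean across the six
    scores.  For each score and each other cluster, a one-sided Welch
    two-sample test checks that the candidate is lower (``classic_anova``
    switches to a two-sided two-group one-way ANOVA; ``pooled`` compares
    against all remaining cells at once).  Every comparison must reach
    ``P < alpha`` for the candidate to be reported as G0.
    """
    x = scores.to_numpy(dtype=float)
    n = x.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} cells")
    labels = None
    for attempt in range(10):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt)
        cand = km.fit_predict(x)
        if len(np.unique(cand)) == k:
            labels = cand
            break
    if labels is None:
        raise RuntimeError("k-means repeatedly produced empty clusters")

    grand = np.array([x[labels == c].mean() for c in range(k)])
    candidate = int(np.argmin(grand))
    others = [c for c in range(k) if c != candidate]
    cand_mask = labels == candidate

    pvals = np.ones((len(PHASE_NAMES), len(others)))
    for si in range(len(PHASE_NAMES)):
        a = x[cand_mask, si]
        for oi, other in enumerate(others):
            b = x[labels == other, si] if not pooled else x[~cand_mask, si]
            if classic_anova:
                res = stats.f_oneway(a, b)
                p = res.pvalue
            else:
                res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
                p = res.pvalue
            pvals[si, oi] = 1.0 if np.isnan(p) else float(p)
    table = pd.DataFrame(
        pvals,
        index=list(PHASE_NAMES),
        columns=[f"cluster_{c}" for c in others],
    )
    all_pass = bool(np.all(pvals < alpha)) if alpha > 0 else False
    ids = [scores.index[i] for i in np.flatnonzero(cand_mask)] if all_pass else []
    return G0Report(
        g0_cell_ids=ids,
        candidate_cluster=candidate,
        p_values=table,
        cluster_labels=labels,
        alpha=alpha,
    )


def spiral_coordinates(
    cycle_pt: np.ndarray, diff_pt: PseudotimeVector | np.ndarray
) -> np.ndarray:
    """Couple cycle and differentiation pseudotime as 3-D spiral points.

    The cyclic pseudotime (in [0, 1)) is wrapped onto the unit circle,
    ``(cos 2*pi*t, sin 2*pi*t)``, and the differentiation pseudotime is the
    z coordinate.  Values outside [0, 1) are wrapped modulo 1 with a
    warning.
    """
    c = np.asarray(cycle_pt, dtype=float)
    z = diff_pt.scores if isinstance(diff_pt, PseudotimeVector) else np.asarray(diff_pt, float)
    if c.shape != z.shape:
        raise ValueError("cycle and differentiation pseudotime must have equal length")
    if np.any((c < 0) | (c >= 1)):
        warnings.warn("cycle pseudotime outside [0, 1); wrapping modulo 1", stacklevel=2)
        c = np.mod(c, 1.0)
    angle = 2.0 * np.pi * c
    return np.column_stack([np.cos(angle), np.sin(angle), z])
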