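"""Cell-cell distance measures.

Two distances drive the pipeline: a symmetric Spearman-correlation distance
used for hierarchical clustering of cells, and an asymmetric
Kullback-Leibler (KL) cost used as the directed edge weight of the
Hamiltonian-path search.  The KL asymmetry encodes the assumption that
differentiation is directional: moving "backwards" from a more to a less
differentiated profile is penalized differently than the forward direction.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


def spearman_distance(
    expr_values: np.ndarray, as_printed: bool = False
) -> np.ndarray:
    """Pairwise Spearman-based cell distance matrix.

    Parameters
    ----------
    expr_values
        ``(n_cells, n_genes)`` matrix (an :class:`ExpressionMatrix.values`
        array or any 2-D float array).
    as_printed
        If False (default) return ``(1 - rho)/2`` so identical cells have
        distance 0; if True return the similarity-like ``(rho + 1)/2``.

    Ties are resolved with average ranks.  A cell whose expression is
    constant across genes has undefined rank correlation; its off-diagonal
    entries are set to the neutral value (rho = 0) with a warning.
    """
    x = np.asarray(expr_values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    ranks = rankdata(x, axis=1)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    flat = norms == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} cell(s) have constant expression; "
            "their rank correlations are set to 0",
            stacklevel=2,
        )
    safe = np.where(flat, 1.0, norms)
    unit = centered / safe[:, None]
    rho = unit @ unit.T
    rho[flat, :] = 0.0
    rho[:, flat] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)
    if as_printed:
        d = (rho + 1.0) / 2.0
    else:
        d = (1.0 - rho) / 2.0
        np.fill_diagonal(d, 0.0)
    return d


def double_center(d: np.ndarray) -> np.ndarray:
    """Classical MDS double centering, ``B = -1/2 J D^2 J``.

    ``D^2`` is the element-wise square of the distance matrix and
    ``J = I - (1/N) 11'``.  Every row and column mean of the result is 0.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("double centering requires a square matrix")
    d2 = d**2
    row = d2.mean(axis=1, keepdims=True)
    col = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    return -0.5 * (d2 - row - col + grand)


def _to_distribution(raw: np.ndarray, pseudocount: float) -> np.ndarray:
    p = np.asarray(raw, dtype=float) + pseudocount
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero vector with pseudocount 0")
    return p / total


def kl_cost(
    p_raw: Sequence[float] | np.ndarray,
    q_raw: Sequence[float] | np.ndarray,
    pseudocount: float = 1e-6,
) -> float:
    """Directed KL divergence between two expression profiles, in nats.

    Each raw nonnegative vector is shifted by ``pseudocount`` and normalized
    to the simplex; the result is ``sum_m p_m ln(p_m / q_m)``, which is >= 0
    and 0 iff the raw vectors are equal.
    """
    p_raw = np.asarray(p_raw, dtype=float)
    q_raw = np.asarray(q_raw, dtype=float)
    if p_raw.shape != q_raw.shape:
        raise ValueError("vectors must have the same length")
    if np.any(p_raw < 0) or np.any(q_raw < 0):
        raise ValueError("expression vectors must be nonnegative")
    p = _to_distribution(p_raw, pseudocount)
    q = _to_distribution(q_raw, pseudocount)
    return float(np.sum(p * (np.log(p) - np.log(q))))


def kl_cost_matrix(
    vectors: np.ndarray | Sequence[Sequence[float]],
    pseudocount: float = 1e-6,
) -> np.ndarray:
    """Full directed KL cost matrix; entry (i, j) = KL(v_i || v_j).

    Computed as ``sum_m p_im ln p_im - sum_m p_im ln p_jm`` via one matrix
    product, with an exactly-zero diagonal.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    if np.any(v < 0):
        raise ValueError("expression vectors must be nonnegative")
    p = v + pseudocount
    totals = p.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise ValueError("cannot normalize an all-zero vector with pseudocount 0")
    p = p / totals
    logp = np.log(p)
    self_term = np.sum(p * logp, axis=1)
    cross = p @ logp.T
    costs = self_term[:, None] - cross
    costs = np.maximum(costs, 0.0)  # clip -0.0 / rounding noise
    np.fill_diagonal(costs, 0.0)
    return costs
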