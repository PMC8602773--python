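"""Gene dynamics along pseudotime.

Genes are ranked against the pseudotime with two [0, 1] dependence measures
that detect non-monotone association — distance correlation (dCor) and the
maximal information coefficient (MIC) — and significant genes are segmented
into hidden on/off expression states with a univariate Gaussian HMM
(Baum-Welch for the transition probabilities, Viterbi for the state path).
Binary state tracks are then clustered into gene modules for heatmap export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .consensus import PseudotimeVector
from .preprocess import ExpressionMatrix

_SD_FLOOR = 1e-3


@dataclass
class GeneScore:
    """Dependence of one gene on pseudotime."""

    gene_id: str
    dcor: float
    mic: float
    kept: bool = False

    @property
    def best(self) -> float:
        return max(self.dcor, self.mic)


@dataclass
class GeneStateTrack:
    """Hidden on/off state sequence for one gene, ordered by pseudotime.

    States are relabeled so that the emission mean increases with the state
    index (state 0 = off / lowly expressed).  ``degenerate`` flags genes
    whose values were all identical, for which a single-state track is
    returned without fitting.
    """

    gene_id: str
    states: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    transition: np.ndarray
    startprob: np.ndarray | None = None
    log_likelihood: float = np.nan
    degenerate: bool = False


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Szekely's sample distance correlation, in [0, 1].

    Pairwise absolute-difference matrices of x and y are double centered;
    dCor is the square root of the normalized inner product.  A constant
    vector has zero distance variance and returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: distance correlation defined as 0", stacklevel=2)
        return 0.0

    def centered(v: np.ndarray) -> np.ndarray:
        d = np.abs(v[:, None] - v[None, :])
        return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()

    a = centered(x)
    b = centered(y)
    dcov2 = (a * b).mean()
    dvarx = (a * a).mean()
    dvary = (b * b).mean()
    denom = np.sqrt(dvarx * dvary)
    if denom <= 0:
        return 0.0
    r2 = dcov2 / denom
    return float(np.sqrt(max(r2, 0.0)))


def _equifreq_bins(v: np.ndarray, k: int) -> np.ndarray:
    """Assign each value to one of k equal-frequency bins by rank."""
    order = np.argsort(v, kind="stable")
    bins = np.empty(len(v), dtype=int)
    bins[order] = (np.arange(len(v)) * k) // len(v)
    return bins


def mic_score(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.6, c: float = 15
) -> float:
    """Maximal information coefficient via an equal-frequency grid search.

    For every grid shape (kx, ky) with kx*ky <= B(n) = n**alpha (and each
    axis capped at ``c`` bins), both axes are partitioned into
    equal-frequency bins, mutual information of the induced joint histogram
    is computed, normalized by log(min(kx, ky)), and the maximum over grids
    is returned.  A noiseless monotone relationship gives 1 exactly (ranks
    coincide on every grid); independent data stay near 0 because the
    normalized information of a product histogram vanishes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if x.shape != y.shape or x.ndim != 1 or n < 10:
        raise ValueError("need two equal-length 1-D vectors with n >= 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    budget = max(4.0, n**alpha)
    k_cap = int(min(c, budget / 2))
    best = 0.0
    for kx in range(2, k_cap + 1):
        bx = _equifreq_bins(x, kx)
        ky_max = int(min(c, budget / kx))
        for ky in range(2, ky_max + 1):
            by = _equifreq_bins(y, ky)
            joint = np.zeros((kx, ky))
            np.add.at(joint, (bx, by), 1.0)
            joint /= n
            px = joint.sum(axis=1)
            py = joint.sum(axis=0)
            nz = joint > 0
            mi = float(
                np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz]))
            )
            best = max(best, mi / np.log(min(kx, ky)))
    return float(min(best, 1.0))


def rank_genes(
    expr: ExpressionMatrix,
    pt: PseudotimeVector | np.ndarray,
    threshold: float = 0.5,
    rule: str = "max",
    mic_alpha: float = 0.6,
) -> list[GeneScore]:
    """Score every gene against the pseudotime and flag the kept subset.

    Returned scores are sorted by max(dCor, MIC) descending.  A gene is kept
    when its selection statistic meets ``threshold``: rule "max" (default)
    uses max(dCor, MIC); rule "both" requires both to pass.
    """
    scores_pt = pt.scores if isinstance(pt, PseudotimeVector) else np.asarray(pt, float)
    if len(scores_pt) != expr.n_cells:
        raise ValueError("pseudotime length does not match cell count")
    out: list[GeneScore] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, gene in enumerate(expr.gene_ids):
            v = expr.values[:, j]
            d = distance_correlation(v, scores_pt)
            m = mic_score(v, scores_pt, alpha=mic_alpha) if np.ptp(v) > 0 else 0.0
            out.append(GeneScore(gene, d, m))
    for gs in out:
        stat = gs.best if rule == "max" else min(gs.dcor, gs.mic)
        gs.kept = stat >= threshold
    out.sort(key=lambda g: (-g.best, g.gene_id))
    return out


def fit_gene_hmm(
    values_ordered: np.ndarray,
    n_states: int = 2,
    max_iter: int = 100,
    tol: float = 1e-4,
    update_emissions: bool = False,
    gene_id: str = "",
) -> GeneStateTrack:
    """Segment one gene's pseudotime-ordered expression into hidden states.

    Emissions are univariate Gaussians initialized from the sorted values
    split into ``n_states`` equal blocks (block means and sds, sd floored at
    1e-3); Baum-Welch then re-estimates the transition matrix (and, if
    ``update_emissions``, the Gaussians) until the log-likelihood gain drops
    below ``tol``; Viterbi decoding returns the MAP state path.  States come
    back relabeled so state means increase with the index.
    """
    v = np.asarray(values_ordered, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("need a 1-D sequence of length >= 4")
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    if np.ptp(v) == 0:
        return GeneStateTrack(
            gene_id=gene_id,
            states=np.zeros(len(v), dtype=int),
            means=np.array([v[0]]),
            sds=np.array([_SD_FLOOR]),
            transition=np.array([[1.0]]),
            degenerate=True,
        )

    blocks = np.array_split(np.sort(v), n_states)
    means = np.array([b.mean() for b in blocks])
    sds = np.array([max(b.std(), _SD_FLOOR) for b in blocks])
    if np.any([b.std() < _SD_FLOOR for b in blocks]):
        warnings.warn("zero-variance initialization block; sd floored at 1e-3", stacklevel=2)

    model = GaussianHMM(
        n_components=n_states,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="st" + ("mc" if update_emissions else ""),
        min_covar=_SD_FLOOR**2,
    )
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    sticky = 0.9
    trans = np.full((n_states, n_states), (1.0 - sticky) / (n_states - 1))
    np.fill_diagonal(trans, sticky)
    model.transmat_ = trans
    model.means_ = means[:, None]
    model.covars_ = (sds**2)[:, None]

    obs = v[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(obs)
    history = list(model.monitor_.history)
    for prev, cur in zip(history, history[1:]):
        if cur < prev - 1e-6:
            raise RuntimeError("Baum-Welch log-likelihood decreased")
    log_lik, states = model.decode(obs, algorithm="viterbi")

    fitted_means = model.means_.ravel()
    fitted_sds = np.sqrt(np.array([np.atleast_2d(c).ravel()[0] for c in model.covars_]))
    order = np.argsort(fitted_means, kind="stable")
    relabel = np.empty(n_states, dtype=int)
    relabel[order] = np.arange(n_states)
    return GeneStateTrack(
        gene_id=gene_id,
        states=relabel[states],
        means=fitted_means[order],
        sds=fitted_sds[order],
        transition=model.transmat_[np.ix_(order, order)],
        startprob=model.startprob_[order],
        log_likelihood=float(log_lik),
    )


def order_gene_modules(
    tracks: list[GeneStateTrack],
    cut_height: float | None = None,
    n_modules: int | None = None,
) -> tuple[list[int], np.ndarray]:
    """Cluster binary state tracks into modules and order them for a heatmap.

    Tracks are compared by Hamming distance and clustered with average
    linkage.  Returns the dendrogram leaf order (indices into ``tracks``)
    and flat module labels obtained by cutting at ``cut_height`` (default
    0.5) or into ``n_modules`` groups.  Three-state tracks are collapsed to
    binary by merging the top two states.
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    lengths = {len(t.states) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("state tracks must have equal length")
    binary = np.array([(t.states >= 1).astype(float) for t in tracks])
    d = pdist(binary, metric="hamming")
    z = linkage(d, method="average")
    leaf_order = [int(i) for i in leaves_list(z)]
    if n_modules is not None:
        labels = fcluster(z, t=n_modules, criterion="maxclust")
    else:
        labels = fcluster(z, t=0.5 if cut_height is None else cut_height,
                          criterion="distance")
    return leaf_order, np.asarray(labels, dtype=int)


def state_matrix(tracks: list[GeneStateTrack]) -> np.ndarray:
    """Stack tracks into a genes x cells integer state matrix."""
    return np.array([t.states for t in tracks], dtype=int)
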