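"""Synthetic trajectory fixtures with the structure the method assumes.

The generators emulate a log-transformed, feature-selected scRNA-seq matrix
for a linear multi-stage differentiation: a fraction of genes rise or fall
monotonically with developmental progress, a fraction switch on or off at a
stage boundary (sigmoid step), and the remainder are pure noise.  Gaussian
noise is added on the log scale and low values suffer thresholded dropout.
Variants add a post-branch-point fate split with arm-specific marker genes,
and a quiescent (G0-like) subpopulation with suppressed cell-cycle phase
scores.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cellcycle import PHASE_NAMES
from .metrics import StageLabels
from .preprocess import ExpressionMatrix


@dataclass
class TrajectoryFixture:
    """A generated expression matrix with its ground truth."""

    expr: ExpressionMatrix
    true_stage: StageLabels
    true_pt: np.ndarray
    branch_id: np.ndarray | None = None
    true_g0_mask: np.ndarray | None = None


def _stages_from_pt(pt: np.ndarray, n_stages: int) -> np.ndarray:
    """Equal-quantile stage bins, monotone in pt by construction."""
    order = np.argsort(pt, kind="stable")
    stages = np.empty(len(pt), dtype=int)
    stages[order] = (np.arange(len(pt)) * n_stages) // len(pt)
    return stages


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def simulate_linear(
    n_cells: int = 150,
    n_stages: int = 3,
    n_genes: int = 300,
    frac_monotone: float = 0.3,
    frac_switch: float = 0.3,
    noise_sd: float = 0.5,
    dropout_p: float = 0.2,
    dropout_threshold: float = 2.0,
    seed: int = 7,
) -> TrajectoryFixture:
    """Linear multi-stage differentiation fixture (the standard fixture).

    ``frac_monotone`` of the genes are linear in the latent pseudotime
    (random slope magnitude 2-6, random sign), ``frac_switch`` are sigmoid
    steps at a random stage boundary, and the rest carry no signal.  Values
    are on a log2-like scale; after adding N(0, noise_sd) noise, entries
    below ``dropout_threshold`` are zeroed with probability ``dropout_p``
    and negatives are clipped at 0.
    """
    if frac_monotone + frac_switch > 1 + 1e-9:
        raise ValueError("gene-class fractions must sum to at most 1")
    if n_stages < 2:
        raise ValueError("need at least 2 stages")
    rng = np.random.default_rng(seed)
    pt = rng.uniform(0.0, 1.0, size=n_cells)
    stages = _stages_from_pt(pt, n_stages)

    n_mono = int(round(frac_monotone * n_genes))
    n_switch = int(round(frac_switch * n_genes))
    values = np.empty((n_cells, n_genes))

    boundaries = np.arange(1, n_stages) / n_stages
    for j in range(n_genes):
        if j < n_mono:
            slope = rng.uniform(2.0, 6.0) * rng.choice([-1.0, 1.0])
            base = rng.uniform(1.0, 3.0)
            signal = base + slope * pt
        elif j < n_mono + n_switch:
            t0 = rng.choice(boundaries)
            direction = rng.choice([-1.0, 1.0])
            lo, hi = rng.uniform(0.5, 1.5), rng.uniform(3.5, 6.0)
            step = _sigmoid(direction * (pt - t0) / 0.05)
            signal = lo + (hi - lo) * step
        else:
            signal = np.full(n_cells, rng.uniform(0.5, 3.0))
        values[:, j] = signal
    values += rng.normal(0.0, noise_sd, size=values.shape)
    if dropout_p > 0:
        low = values < dropout_threshold
        drop = rng.random(values.shape) < dropout_p
        values[low & drop] = 0.0
    values = np.clip(values, 0.0, None)

    expr = ExpressionMatrix(
        values,
        [f"cell_{i:04d}" for i in range(n_cells)],
        [f"gene_{j:04d}" for j in range(n_genes)],
    )
    return TrajectoryFixture(
        expr=expr,
        true_stage=StageLabels(stages, ns=n_stages),
        true_pt=pt,
    )


def simulate_branch(
    n_cells: int = 150,
    n_stages: int = 3,
    n_genes: int = 300,
    frac_monotone: float = 0.3,
    frac_switch: float = 0.2,
    frac_branch: float = 0.3,
    branch_at: float = 0.5,
    noise_sd: float = 0.5,
    dropout_p: float = 0.2,
    dropout_threshold: float = 2.0,
    seed: int = 7,
) -> TrajectoryFixture:
    """Linear trunk with a binary fate split after ``branch_at``.

    Every cell draws an arm label (Bernoulli 1/2); ``frac_branch`` of the
    genes are arm markers, half per arm, that ramp up only in cells of that
    arm past the branch point and stay at baseline elsewhere.  The shared
    trunk program is as in :func:`simulate_linear`.
    """
    if not 0.0 < branch_at < 1.0:
        raise ValueError("branch_at must be in (0, 1)")
    if frac_monotone + frac_switch + frac_branch > 1 + 1e-9:
        raise ValueError("gene-class fractions must sum to at most 1")
    rng = np.random.default_rng(seed)
    pt = rng.uniform(0.0, 1.0, size=n_cells)
    stages = _stages_from_pt(pt, n_stages)
    arm = rng.integers(0, 2, size=n_cells)
    past = pt > branch_at

    n_mono = int(round(frac_monotone * n_genes))
    n_switch = int(round(frac_switch * n_genes))
    n_branch = int(round(frac_branch * n_genes))
    values = np.empty((n_cells, n_genes))
    boundaries = np.arange(1, n_stages) / n_stages
    for j in range(n_genes):
        if j < n_mono:
            slope = rng.uniform(2.0, 6.0) * rng.choice([-1.0, 1.0])
            base = rng.uniform(1.0, 3.0)
            signal = base + slope * pt
        elif j < n_mono + n_switch:
            t0 = rng.choice(boundaries)
            direction = rng.choice([-1.0, 1.0])
            lo, hi = rng.uniform(0.5, 1.5), rng.uniform(3.5, 6.0)
            signal = lo + (hi - lo) * _sigmoid(direction * (pt - t0) / 0.05)
        elif j < n_mono + n_switch + n_branch:
            marker_arm = 0 if (j - n_mono - n_switch) < n_branch // 2 else 1
            base = rng.uniform(0.5, 1.0)
            amp = rng.uniform(4.0, 7.0)
            ramp = np.clip((pt - branch_at) / (1.0 - branch_at), 0.0, 1.0)
            signal = base + amp * ramp * ((arm == marker_arm) & past)
        else:
            signal = np.full(n_cells, rng.uniform(0.5, 3.0))
        values[:, j] = signal
    values += rng.normal(0.0, noise_sd, size=values.shape)
    if dropout_p > 0:
        low = values < dropout_threshold
        drop = rng.random(values.shape) < dropout_p
        values[low & drop] = 0.0
    values = np.clip(values, 0.0, None)

    expr = ExpressionMatrix(
        values,
        [f"cell_{i:04d}" for i in range(n_cells)],
        [f"gene_{j:04d}" for j in range(n_genes)],
    )
    return TrajectoryFixture(
        expr=expr,
        true_stage=StageLabels(stages, ns=n_stages),
        true_pt=pt,
        branch_id=arm,
    )


_PHASE_BOOSTS = {
    # each cycling phase elevates its own score and the adjoining
    # boundary score, mirroring how phase annotations overlap
    "G1": ("G1", "G1/S"),
    "S": ("S", "G1/S"),
    "G2": ("G2", "G2/M"),
    "M": ("M", "G2/M"),
}


def simulate_cycle_scores(
    n_cycling: int = 40,
    n_g0: int = 20,
    mu_cycling: float = 5.0,
    mu_g0: float = 1.0,
    sd: float = 0.2,
    phase_boost: float = 2.0,
    seed: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Six-phase score table with a quiescent subpopulation.

    Cycling cells are assigned round-robin to the four cycle phases (G1, S,
    G2, M); every phase score starts at N(mu_cycling, sd) and the cell's own
    phase columns are raised by ``phase_boost``, so the cycling population
    forms four phase clusters as k-means with k = 5 assumes.  Quiescent
    cells draw all six scores from N(mu_g0, sd).  Returns the score table
    (cycling cells first) and the boolean G0 mask.
    """
    if mu_cycling <= mu_g0:
        raise ValueError("mu_cycling must exceed mu_g0")
    rng = np.random.default_rng(seed)
    n = n_cycling + n_g0
    mask = np.zeros(n, dtype=bool)
    mask[n_cycling:] = True
    mus = np.where(mask, mu_g0, mu_cycling)[:, None]
    base = np.broadcast_to(mus, (n, len(PHASE_NAMES))).copy()
    cycle_phases = list(_PHASE_BOOSTS)
    col = {p: i for i, p in enumerate(PHASE_NAMES)}
    for i in range(n_cycling):
        for boosted in _PHASE_BOOSTS[cycle_phases[i % 4]]:
            base[i, col[boosted]] += phase_boost
    scores = base + rng.normal(0.0, sd, size=base.shape) if sd > 0 else base
    table = pd.DataFrame(
        scores,
        index=[f"cell_{i:04d}" for i in range(n)],
        columns=list(PHASE_NAMES),
    )
    return table, mask
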