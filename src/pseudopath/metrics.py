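"""Evaluation of inferred orderings against ordered stage labels.

Four metrics compare a pseudotemporal ordering with known, ordered
developmental stages (e.g. qNSC -> aNSC -> NPC): the change index (CI)
counts adjacent stage switches along the ordering; the bubble sort index
(BI) counts cross-stage inversions (adjacent swaps needed to reach a
stage-sorted ordering); Kendall correlation (KC) is tau-b between
pseudotime and stage index; and the pseudo-temporal ordering score (POS) is
the net cross-stage pair concordance.  Because consensus pseudotime has an
arbitrary global direction, each metric reports the better of the ordering
and its reverse unless a signed variant is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau


@dataclass
class StageLabels:
    """Per-cell stage indices 0..ns-1 following the known developmental order."""

    stages: np.ndarray
    ns: int

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=int)
        present = np.unique(self.stages)
        if self.ns < 2:
            raise ValueError("need at least 2 stages")
        if not np.array_equal(present, np.arange(self.ns)):
            raise ValueError(
                f"stages must cover 0..{self.ns - 1}; found {present.tolist()}"
            )

    @classmethod
    def from_names(
        cls, names: list[str], stage_order: list[str]
    ) -> "StageLabels":
        index = {s: i for i, s in enumerate(stage_order)}
        unknown = sorted(set(names) - set(index))
        if unknown:
            raise ValueError(f"labels not in the declared stage order: {unknown}")
        return cls(np.array([index[s] for s in names]), ns=len(stage_order))

    def __len__(self) -> int:
        return len(self.stages)


@dataclass
class EvaluationReport:
    ci: float
    bi: float
    kc: float
    pos: float


def _check_order(order: np.ndarray, labels: StageLabels) -> np.ndarray:
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(len(labels))):
        raise ValueError("order must be a permutation of all cells")
    return order


def change_index(
    order: np.ndarray, labels: StageLabels, as_printed: bool = False
) -> float:
    """Change index: 1 for a block-contiguous ordering, 0 at maximal alternation.

    With s adjacent stage changes along the ordering, CI is
    ``1 - (s - ns + 1)/(N - ns)``, which reaches exactly 1 when the stages
    form contiguous blocks (s = ns - 1) and exactly 0 when every adjacent
    pair differs (s = N - 1).  ``as_printed`` substitutes the variant
    ``1 - (s - ns - 1)/(N - ns)``, which shifts the scale by 2/(N - ns).
    The count of adjacent changes is unchanged by reversal, so the metric is
    direction-free.  The result is clamped to [0, 1].
    """
    order = _check_order(order, labels)
    n, ns = len(labels), labels.ns
    if n <= ns:
        raise ValueError("need more cells than stages")
    seq = labels.stages[order]
    s = int(np.count_nonzero(seq[1:] != seq[:-1]))
    if as_printed:
        ci = 1.0 - (s - ns - 1) / (n - ns)
    else:
        ci = 1.0 - (s - ns + 1) / (n - ns)
    return float(np.clip(ci, 0.0, 1.0))


def _cross_stage_inversions(seq: np.ndarray) -> tuple[int, int]:
    """Count cross-stage inversions and total cross-stage pairs in seq."""
    later_gt = seq[:, None] > seq[None, :]
    upper = np.triu(np.ones((len(seq), len(seq)), dtype=bool), k=1)
    s = int(np.count_nonzero(later_gt & upper))  # seq[i] > seq[j], i < j
    total = int(np.count_nonzero((seq[:, None] != seq[None, :]) & upper))
    return s, total


def bubble_sort_index(
    order: np.ndarray, labels: StageLabels, signed_direction: bool = False
) -> float:
    """Bubble sort index: 1 - (cross-stage inversions / worst case).

    s counts pairs placed in the wrong stage order (within-stage order is
    free); S is the total number of cross-stage pairs, attained by the fully
    reversed ordering.  The better of the ordering and its reverse is
    reported (their inversion counts sum to S) unless ``signed_direction``
    keeps the given direction.
    """
    order = _check_order(order, labels)
    seq = labels.stages[order]
    if len(np.unique(seq)) < 2:
        raise ValueError("BI undefined for single-stage labels")
    s, total = _cross_stage_inversions(seq)
    bi = 1.0 - s / total
    if signed_direction:
        return float(bi)
    return float(max(bi, 1.0 - bi))


def kendall_correlation(
    pt: np.ndarray, labels: StageLabels, signed: bool = False
) -> float:
    """Tie-corrected Kendall tau-b between pseudotime and stage index.

    The absolute value is reported by default because the pseudotime
    direction is arbitrary; ``signed`` returns the raw coefficient.
    """
    pt = np.asarray(pt, dtype=float)
    if len(pt) != len(labels):
        raise ValueError("length mismatch")
    if np.ptp(pt) == 0:
        raise ValueError("constant pseudotime")
    tau = kendalltau(pt, labels.stages).statistic
    tau = 0.0 if np.isnan(tau) else float(tau)
    return tau if signed else abs(tau)


def pos_score(
    order: np.ndarray, labels: StageLabels, signed_direction: bool = False
) -> float:
    """Pseudo-temporal ordering score: net cross-stage pair concordance.

    (concordant - discordant cross-stage pairs) / total cross-stage pairs;
    identically ``2*BI - 1`` under this module's definitions.  The better
    direction is reported unless ``signed_direction``.
    """
    bi = bubble_sort_index(order, labels, signed_direction=True)
    pos = 2.0 * bi - 1.0
    if signed_direction:
        return float(pos)
    return float(max(pos, -pos))


def evaluate_ordering(
    pt_scores: np.ndarray, labels: StageLabels
) -> EvaluationReport:
    """Compute CI, BI, KC, and POS for a pseudotime vector."""
    pt_scores = np.asarray(pt_scores, dtype=float)
    order = np.argsort(pt_scores, kind="stable")
    return EvaluationReport(
        ci=change_index(order, labels),
        bi=bubble_sort_index(order, labels),
        kc=kendall_correlation(pt_scores, labels),
        pos=pos_score(order, labels),
    )
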