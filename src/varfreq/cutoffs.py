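"""Cutoff selection by mutual information against a truth set.

Each candidate cutoff turns per-site confidence scores (one-sided
max-confident frequency, or max-confident frequency difference) into binary
calls; the candidate whose call/truth contingency table carries the most
mutual information is selected.  ROC points accompany the profile so the
trade-off behind the selected cutoff is visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Call-vs-truth counts: rows are calls (+/-), columns truth (+/-)."""

    call_pos_truth_pos: int
    call_pos_truth_neg: int
    call_neg_truth_pos: int
    call_neg_truth_neg: int

    def __post_init__(self) -> None:
        if min(self.as_array().ravel()) < 0:
            raise ValueError("contingency counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                [self.call_pos_truth_pos, self.call_pos_truth_neg],
                [self.call_neg_truth_pos, self.call_neg_truth_neg],
            ],
            dtype=float,
        )

    @property
    def total(self) -> int:
        return (
            self.call_pos_truth_pos
            + self.call_pos_truth_neg
            + self.call_neg_truth_pos
            + self.call_neg_truth_neg
        )


@dataclass(frozen=True)
class RocPoint:
    cutoff: float
    tpr: float
    fpr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tpr <= 1.0 and 0.0 <= self.fpr <= 1.0):
            raise ValueError("rates must lie in [0, 1]")


def mutual_information(
    table: ContingencyTable2x2, pseudocount: float = 0.0
) -> float:
    """Plug-in mutual information (bits) of the empirical call/truth joint.

    ``pseudocount`` adds a Laplace count to every cell, useful for tiny
    validation sets; the default is the raw plug-in estimate.  Uses the
    0*log(0) = 0 convention.
    """
    counts = table.as_array() + pseudocount
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty contingency table")
    joint = counts / total
    rows = joint.sum(axis=1, keepdims=True)
    cols = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log2(joint / (rows * cols))
    return float(np.nansum(terms))


def build_contingency(
    calls: Sequence[bool], truth: Sequence[bool]
) -> ContingencyTable2x2:
    """Tally aligned binary calls against binary truth labels."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape or calls.ndim != 1:
        raise ValueError("calls and truth must be 1-D and of equal length")
    if calls.size == 0:
        raise ValueError("empty inputs")
    return ContingencyTable2x2(
        call_pos_truth_pos=int(np.sum(calls & truth)),
        call_pos_truth_neg=int(np.sum(calls & ~truth)),
        call_neg_truth_pos=int(np.sum(~calls & truth)),
        call_neg_truth_neg=int(np.sum(~calls & ~truth)),
    )


def _roc_point(table: ContingencyTable2x2, cutoff: float) -> RocPoint:
    pos = table.call_pos_truth_pos + table.call_neg_truth_pos
    neg = table.call_pos_truth_neg + table.call_neg_truth_neg
    if pos == 0:
        logger.warning("no truth-positives: TPR undefined, reported as 0")
        tpr = 0.0
    else:
        tpr = table.call_pos_truth_pos / pos
    if neg == 0:
        logger.warning("no truth-negatives: FPR undefined, reported as 0")
        fpr = 0.0
    else:
        fpr = table.call_pos_truth_neg / neg
    return RocPoint(cutoff=cutoff, tpr=tpr, fpr=fpr)


@dataclass(frozen=True)
class CutoffSelection:
    """MI-maximizing cutoff plus the full MI/ROC profile over candidates."""

    cutoff: float
    mi_profile: np.ndarray  # one MI value (bits) per candidate
    roc_points: tuple[RocPoint, ...]


def roc_curve(
    candidates: Sequence[float],
    item_scores: Sequence[float],
    truth: Sequence[bool],
) -> list[RocPoint]:
    """One ROC point per candidate cutoff (call = score >= cutoff)."""
    scores = np.asarray(item_scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("item_scores and truth must have equal length")
    points = []
    for c in candidates:
        table = build_contingency(scores >= c, truth)
        points.append(_roc_point(table, float(c)))
    return points


def select_cutoff(
    candidates: Sequence[float],
    item_scores: Sequence[float],
    truth: Sequence[bool],
    pseudocount: float = 0.0,
) -> CutoffSelection:
    """Pick the candidate cutoff maximizing mutual information with truth.

    Ties resolve toward the smallest cutoff, which keeps more items above
    threshold for downstream validation.
    """
    candidates = [float(c) for c in candidates]
    if not candidates:
        raise ValueError("no candidate cutoffs")
    scores = np.asarray(item_scores, dtype=float)
    truth_arr = np.asarray(truth, dtype=bool)
    mi_values = np.empty(len(candidates))
    roc_points = []
    for i, c in enumerate(candidates):
        table = build_contingency(scores >= c, truth_arr)
        mi_values[i] = mutual_information(table, pseudocount)
        roc_points.append(_roc_point(table, c))
    order = sorted(range(len(candidates)), key=lambda i: (-mi_values[i], candidates[i]))
    best = order[0]
    return CutoffSelection(
        cutoff=candidates[best],
        mi_profile=mi_values,
        roc_points=tuple(roc_points),
    )
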