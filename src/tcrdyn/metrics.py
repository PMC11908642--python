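"""Threshold-free binary-classification metrics, implemented from first principles.

``auroc`` is the Mann–Whitney rank statistic: the probability that a uniformly
chosen positive outscores a uniformly chosen negative, with ties credited 1/2.
``auprc`` is the area under the precision–recall step curve, accumulated as
sum(delta-recall x precision-at-threshold) over distinct thresholds in
descending score order with tied scores grouped (no linear interpolation);
this is the average-precision convention, so numbers are comparable across
standard implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class MetricUndefinedError(ValueError):
    """Raised when a metric is requested on degenerate inputs (single class)."""


@dataclass(frozen=True)
class ScoredLabels:
    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D arrays of equal length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int64))


def _average_ranks(x: np.ndarray) -> np.ndarray:
    """1-based ranks with ties assigned the average rank of their group."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sorted_x = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0  # mean of 1-based ranks i+1..j+1
        i = j + 1
    return ranks


def auroc(sl: ScoredLabels) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney U) formulation."""
    n_pos = int(sl.labels.sum())
    n_neg = len(sl.labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("AUROC requires at least one positive and one negative")
    ranks = _average_ranks(sl.scores)
    u = ranks[sl.labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auprc(sl: ScoredLabels) -> float:
    """Area under the precision–recall step curve (average precision)."""
    n_pos = int(sl.labels.sum())
    if n_pos == 0:
        raise MetricUndefinedError("AUPRC requires at least one positive")
    order = np.argsort(-sl.scores, kind="stable")
    scores = sl.scores[order]
    labels = sl.labels[order]

    # Group tied scores: evaluate precision/recall only at distinct thresholds.
    distinct = np.nonzero(np.diff(scores))[0]
    threshold_idx = np.concatenate([distinct, [len(scores) - 1]])

    tp = np.cumsum(labels)[threshold_idx].astype(float)
    fp = np.cumsum(1 - labels)[threshold_idx].astype(float)
    precision = tp / (tp + fp)
    recall = tp / n_pos
    delta_recall = np.diff(np.concatenate([[0.0], recall]))
    return float(np.sum(delta_recall * precision))
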