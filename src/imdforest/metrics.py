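"""Scoring selections and rankings against ground truth."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MetricsReport",
    "precision_recall",
    "pr_auc",
    "top_k_tpr",
    "overlap_coefficient",
    "aggregate_reports",
]


@dataclass
class MetricsReport:
    recall: float
    precision: float
    pr_auc: float
    model_size: int
    top_k_tpr: float | None = None
    overlap_coefficient: float | None = None


def precision_recall(selected, truth) -> tuple[float, float]:
    """Exact set arithmetic: precision = tp/(tp+fp), recall = tp/(tp+fn).

    An empty selection has undefined precision, reported as 0 with a warning.
    """
    selected = set(selected)
    truth = set(truth)
    if not truth:
        raise ValueError("truth set must be nonempty")
    tp = len(selected & truth)
    if not selected:
        warnings.warn("empty selection: precision undefined, reported as 0")
        return 0.0, 0.0
    return tp / len(selected), tp / len(truth)


def pr_auc(scores, truth_mask) -> float:
    """Area under the precision-recall curve of the ranking induced by
    `scores` (higher = more likely positive).

    Ties are broken by stable input order, and the curve is integrated
    stepwise: AUC = sum_k (R_k - R_{k-1}) P_k over the ranked prefix.  An
    all-equal score vector carries no ranking information; the prevalence
    baseline is returned with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if scores.shape != truth_mask.shape:
        raise ValueError("scores and truth must align")
    n_pos = int(truth_mask.sum())
    if n_pos == 0:
        raise ValueError("truth set must be nonempty")
    if np.all(scores == scores[0]):
        warnings.warn("all scores equal: returning prevalence baseline")
        return n_pos / scores.size
    order = np.argsort(-scores, kind="stable")
    hits = truth_mask[order]
    tp = np.cumsum(hits)
    ranks = np.arange(1, scores.size + 1)
    precision_at = tp / ranks
    # recall increases by 1/n_pos exactly at positive ranks
    return float(precision_at[hits].sum() / n_pos)


def top_k_tpr(scores, truth_mask, k: int) -> float:
    """|top-k of the ranking intersected with truth| / |truth|."""
    scores = np.asarray(scores, dtype=float)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_pos = int(truth_mask.sum())
    if n_pos == 0:
        raise ValueError("truth set must be nonempty")
    if k > scores.size:
        warnings.warn("k exceeds the number of candidates; clipped")
        k = scores.size
    order = np.argsort(-scores, kind="stable")[:k]
    return float(truth_mask[order].sum() / n_pos)


def overlap_coefficient(a, b) -> float:
    """Szymkiewicz-Simpson coefficient |A & B| / min(|A|, |B|)."""
    a, b = set(a), set(b)
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Mean and SD over replicate runs, one entry per metric."""
    out = {}
    for key in ("pr_auc", "precision", "recall", "model_size"):
        vals = np.asarray([getattr(r, key) for r in reports], dtype=float)
        out[key] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    return out
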