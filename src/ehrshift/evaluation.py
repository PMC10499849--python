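"""Metrics and distribution-shift diagnostics.

Performance is summarized by AUROC (Mann-Whitney rank statistic, ties
counted as half-concordant), AUPRC (step-interpolated area under the
precision-recall curve) and accuracy at the 0.5 threshold — the natural
threshold for a balanced case-control design.  Shift diagnostics compare
per-code occurrence distributions between environments, before and after
reweighting, and track performance over coarse time periods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .data import PaddedBatch
from .reweighting import code_distribution

__all__ = [
    "MetricReport",
    "ShiftAudit",
    "auroc",
    "compute_metrics",
    "audit_shift",
    "performance_over_periods",
]


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (equals the Mann-Whitney U statistic
    normalized by the number of positive-negative pairs)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC is undefined when only one class is present")
    return float(roc_auc_score(labels, scores))


@dataclass(frozen=True)
class MetricReport:
    """AUROC / AUPRC / accuracy for one scored patient set."""

    auroc: float
    auprc: float
    accuracy: float
    n: int
    variant: str = ""

    def to_dict(self) -> dict[str, float]:
        return {
            "auroc": self.auroc,
            "auprc": self.auprc,
            "accuracy": self.accuracy,
            "n": self.n,
        }


def compute_metrics(
    scores: np.ndarray, labels: np.ndarray, variant: str = ""
) -> MetricReport:
    """Score a set of predicted risks against binary outcome labels.

    AUROC and AUPRC require both classes; accuracy (threshold 0.5) is
    always defined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    acc = float(((scores >= 0.5).astype(int) == labels).mean())
    if len(np.unique(labels)) < 2:
        raise ValueError(
            "AUROC/AUPRC undefined with a single class "
            f"(accuracy would be {acc:.3f})"
        )
    return MetricReport(
        auroc=float(roc_auc_score(labels, scores)),
        auprc=float(average_precision_score(labels, scores)),
        accuracy=acc,
        n=int(labels.shape[0]),
        variant=variant,
    )


@dataclass
class ShiftAudit:
    """Per-code rates and distances between pre-/post-shift distributions.

    ``table`` columns: code index, ``d_pre1`` (pre-shift, unit weights),
    ``d_post``, ``d_preW`` (pre-shift under the supplied weights) and the
    post/pre rate ratio.  Distances compare each pre-shift variant to the
    post-shift distribution.
    """

    table: pd.DataFrame
    l1_pre1_post: float
    l2_pre1_post: float
    l1_preW_post: float
    l2_preW_post: float

    def to_dict(self) -> dict[str, float]:
        return {
            "l1_pre1_post": self.l1_pre1_post,
            "l2_pre1_post": self.l2_pre1_post,
            "l1_preW_post": self.l1_preW_post,
            "l2_preW_post": self.l2_preW_post,
        }


def audit_shift(
    pre_batch: PaddedBatch,
    post_batch: PaddedBatch,
    weights: np.ndarray | None = None,
) -> ShiftAudit:
    """Quantify the code-distribution shift and how far weighting closes it."""
    if pre_batch.C != post_batch.C:
        raise ValueError("batches use different vocabularies")
    d_pre1 = code_distribution(pre_batch).d
    d_post = code_distribution(post_batch).d
    d_preW = code_distribution(pre_batch, weights).d if weights is not None else d_pre1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_pre1 > 0, d_post / d_pre1, np.nan)
    table = pd.DataFrame(
        {
            "code": np.arange(pre_batch.C),
            "d_pre1": d_pre1,
            "d_post": d_post,
            "d_preW": d_preW,
            "rate_ratio": ratio,
        }
    )
    return ShiftAudit(
        table=table,
        l1_pre1_post=float(np.abs(d_pre1 - d_post).sum()),
        l2_pre1_post=float(np.linalg.norm(d_pre1 - d_post)),
        l1_preW_post=float(np.abs(d_preW - d_post).sum()),
        l2_preW_post=float(np.linalg.norm(d_preW - d_post)),
    )


def performance_over_periods(model, batch: PaddedBatch) -> pd.DataFrame:
    """Per-period metrics for a batch carrying period tags.

    Rows where a period contains a single outcome class keep accuracy but
    flag AUROC/AUPRC as undefined (NaN) rather than being dropped.
    """
    if batch.periods is None:
        raise ValueError("batch has no period tags")
    scores = model.predict_risk(batch)
    rows = []
    for period in np.unique(batch.periods):
        sel = batch.periods == period
        y, s = batch.labels[sel], scores[sel]
        acc = float(((s >= 0.5).astype(int) == y).mean())
        if len(np.unique(y)) < 2:
            rows.append(
                {"period": int(period), "auroc": np.nan, "auprc": np.nan,
                 "accuracy": acc, "n": int(sel.sum()), "undefined": True}
            )
        else:
            rep = compute_metrics(s, y)
            rows.append(
                {"period": int(period), "auroc": rep.auroc, "auprc": rep.auprc,
                 "accuracy": rep.accuracy, "n": rep.n, "undefined": False}
            )
    return pd.DataFrame(rows)
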