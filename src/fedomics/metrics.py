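"""Classification metric suite for case/control model evaluation.

All metrics are implemented directly from their definitions so that the
pipeline's headline numbers do not depend on any third-party metric
conventions; the test suite cross-checks them against scikit-learn and
brute-force oracles.

Conventions fixed here (they matter on tied scores and degenerate inputs):

* ``auc_pr`` uses the average-precision formulation — the sum over
  descending-score threshold groups of (recall increment x precision at
  that threshold); tied scores enter the curve as one group.
* ``roc_auc`` uses the Mann-Whitney pair-counting formulation; tied
  case/control pairs count 1/2.
* Threshold metrics use ``scores >= threshold`` as the positive call;
  any metric with a zero denominator (precision with no positive calls,
  F-beta with P=R=0, MCC with a degenerate confusion matrix) is 0.
* ``log_loss`` clips probabilities to ``[1e-15, 1 - 1e-15]``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "MetricReport",
    "auc_pr",
    "roc_auc",
    "threshold_metrics",
    "log_loss",
    "compute_report",
]

_EPS = 1e-15


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels.astype(np.int64)


@dataclass(frozen=True)
class MetricReport:
    """One row of the evaluation tables: the full metric suite."""

    roc_auc: float
    auc_pr: float
    balanced_accuracy: float
    precision: float
    recall: float
    f_half: float
    f_one: float
    f_two: float
    log_loss: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __post_init__(self) -> None:
        for name in ("roc_auc", "auc_pr", "balanced_accuracy", "precision", "recall"):
            v = getattr(self, name)
            if not (-1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.log_loss < 0:
            raise ValueError("log_loss must be >= 0")
        if not (-1 - 1e-12 <= self.mcc <= 1 + 1e-12):
            raise ValueError("mcc outside [-1, 1]")


def auc_pr(labels, scores) -> float:
    """Area under the precision-recall curve (average precision).

    AP = sum_k (R_k - R_{k-1}) * P_k over thresholds descending through the
    distinct scores; samples sharing a score form a single threshold group.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group boundaries: last index of each tied block
    boundary = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([boundary, [len(s) - 1]])
    tp = np.cumsum(y)[ends].astype(np.float64)
    n_called = (ends + 1).astype(np.float64)
    total_pos = float(labels.sum())
    precision = tp / n_called
    recall = tp / total_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def roc_auc(labels, scores) -> float:
    """Mann-Whitney ROC-AUC: fraction of (case, control) pairs ranked
    correctly, ties counted half."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    ranks = rankdata(scores)  # average ranks handle ties
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    rank_sum = float(ranks[labels == 1].sum())
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def threshold_metrics(labels, scores, threshold: float = 0.5) -> dict[str, float]:
    """Confusion-matrix metrics at ``scores >= threshold``.

    Returns balanced accuracy, precision, recall, F0.5/F1/F2 and MCC.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    pred = scores >= threshold
    tp = float(np.sum(pred & (labels == 1)))
    fp = float(np.sum(pred & (labels == 0)))
    fn = float(np.sum(~pred & (labels == 1)))
    tn = float(np.sum(~pred & (labels == 0)))

    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    specificity = tn / (tn + fp) if tn + fp > 0 else 0.0
    balanced = 0.5 * (recall + specificity)

    def f_beta(beta: float) -> float:
        denom = beta * beta * precision + recall
        if denom == 0.0:
            return 0.0
        return (1 + beta * beta) * precision * recall / denom

    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0.0 else (tp * tn - fp * fn) / np.sqrt(denom)

    return {
        "balanced_accuracy": balanced,
        "precision": precision,
        "recall": recall,
        "f_half": f_beta(0.5),
        "f_one": f_beta(1.0),
        "f_two": f_beta(2.0),
        "mcc": float(mcc),
    }


def log_loss(labels, probabilities) -> float:
    """Mean negative log-likelihood with probabilities clipped to
    ``[1e-15, 1 - 1e-15]``."""
    labels = np.asarray(labels, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log(1.0 - p)))


def compute_report(labels, scores, threshold: float = 0.5) -> MetricReport:
    """Evaluate the full metric suite for one model on one test set."""
    tm = threshold_metrics(labels, scores, threshold)
    return MetricReport(
        roc_auc=roc_auc(labels, scores),
        auc_pr=auc_pr(labels, scores),
        log_loss=log_loss(labels, scores),
        **tm,
    )
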