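"""ROI-level classification metrics and model selection.

Classification is an interval rule on the pooled activation q: a ROI is
called positive when q lies inside [alpha, alpha + beta] — values above the
upper bound count as overdetection and are called negative.  For the ROC
curve q itself serves as the scalar score (a monotone surrogate below the
upper bound).  Model selection follows highest validation specificity, with
F1 and then the earlier epoch breaking ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = ["MetricsReport", "classify_roi", "compute_metrics", "select_model"]


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    auc_roc: float | None    # None when only one class is present
    epoch: int = -1


def classify_roi(q: float, p=None) -> int:
    """Interval rule: 1 iff alpha <= q <= alpha + beta (endpoints inclusive)."""
    from .compsegnet import TransferParams
    p = p or TransferParams()
    return int(p.alpha <= q <= p.upper)


def compute_metrics(y_true, y_pred, scores) -> MetricsReport:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("inputs must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = len(y_true)
    accuracy = (tp + tn) / n if n else float("nan")
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if (precision + sensitivity) else 0.0)
    auc = None
    if len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, scores))
    return MetricsReport(accuracy, sensitivity, specificity, f1, auc)


def select_model(per_epoch: list[MetricsReport]) -> int:
    """Pick the epoch with highest specificity; ties by F1, then earliest."""
    if not per_epoch:
        raise ValueError("need at least one epoch of metrics")
    best = 0
    for i, r in enumerate(per_epoch[1:], start=1):
        b = per_epoch[best]
        if (r.specificity, r.f1) > (b.specificity, b.f1):
            best = i
    return best
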