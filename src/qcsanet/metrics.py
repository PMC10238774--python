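"""Binary-classification evaluation from confusion counts.

Positive class is the disease class (label 1).  All derived statistics are
computed directly from the TP/TN/FP/FN counts; AUC is the Mann-Whitney
rank statistic on the scores (probability that a random positive outranks
a random negative, ties counted half).  Undefined ratios (zero
denominators) are reported as NaN with a warning, never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["MetricsReport", "compute_metrics", "roc_auc", "f1_score_from_pr"]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float
    auc: float
    kappa: float

    def as_dict(self) -> dict:
        return asdict(self)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def f1_score_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean ``2 P R / (P + R)``."""
    return _ratio(2.0 * precision * recall, precision + recall, "F1")


def roc_auc(labels, scores) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined with a single class; reporting NaN",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(labels, predicted_labels, scores=None) -> MetricsReport:
    """Full evaluation report from labels, hard predictions and scores.

    ``labels``/``predicted_labels`` in {0, 1} with 1 the positive (disease)
    class; ``scores`` are the continuous decision values used for AUC (NaN
    if omitted).  Cohen's kappa is the chance-corrected agreement
    ``(p_o - p_e) / (1 - p_e)``.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must align")
    tp = int(((y == 1) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    n = tp + tn + fp + fn
    accuracy = _ratio(tp + tn, n, "accuracy")
    precision = _ratio(tp, tp + fp, "precision")
    recall = _ratio(tp, tp + fn, "recall")
    f1 = f1_score_from_pr(precision, recall) if precision + recall > 0 else float("nan")
    specificity = _ratio(tn, tn + fp, "specificity")
    if scores is not None:
        auc = roc_auc(y, scores)
    else:
        auc = float("nan")
    p_o = accuracy
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n) if n else float("nan")
    kappa = _ratio(p_o - p_e, 1.0 - p_e, "kappa") if n else float("nan")
    return MetricsReport(tp=tp, tn=tn, fp=fp, fn=fn, accuracy=accuracy,
                         precision=precision, recall=recall, f1=f1,
                         specificity=specificity, auc=auc, kappa=kappa)
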