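"""Pixel-level evaluation statistics: Acc, SE, SP, AUC, and the paired
two-tailed t-test used to compare per-image metrics between models.

Acc = (TP+TN)/(TP+FN+FP+TN), SE = TP/(TP+FN), SP = TN/(TN+FP); AUC is the
area under the ROC curve of the vessel-class probability against the
reference mask (Mann-Whitney convention for ties). Metrics are computed
over all pixels by default; pass ``roi`` to restrict to a field-of-view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import DegenerateTestError, InputError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "roc_auc",
    "paired_two_tailed_ttest",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def _binary(arr, name):
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise InputError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def confusion(mask_pred, mask_ref, roi=None) -> ConfusionCounts:
    """Pixel tallies with vessel encoded as 1; ``roi`` (binary) restricts
    the evaluated region."""
    p = _binary(mask_pred, "mask_pred")
    r = _binary(mask_ref, "mask_ref")
    if p.shape != r.shape:
        raise InputError(f"mask shapes differ: {p.shape} vs {r.shape}")
    if roi is not None:
        m = _binary(roi, "roi")
        if m.shape != p.shape:
            raise InputError(f"roi shape {m.shape} differs from masks {p.shape}")
        p, r = p[m], r[m]
    return ConfusionCounts(
        tp=int(np.sum(p & r)), fp=int(np.sum(p & ~r)),
        tn=int(np.sum(~p & ~r)), fn=int(np.sum(~p & r)))


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined on empty counts")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no reference vessel pixels")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no reference background pixels")
    return c.tn / (c.tn + c.fp)


def roc_auc(prob_vessel, mask_ref, roi=None) -> float:
    """Trapezoidal ROC area of the vessel-probability map; equals
    P(score+ > score-) + 0.5 P(tie) over vessel/background pixel pairs."""
    s = np.asarray(prob_vessel, dtype=float).ravel()
    r = _binary(mask_ref, "mask_ref").ravel()
    if s.size != r.size:
        raise InputError("probability map and reference mask sizes differ")
    if roi is not None:
        m = _binary(roi, "roi").ravel()
        s, r = s[m], r[m]
    if r.all() or not r.any():
        raise UndefinedMetricError("AUC undefined: reference contains a single class")
    return float(roc_auc_score(r.astype(int), s))


def paired_two_tailed_ttest(xs, ys) -> tuple[float, float]:
    """Paired-samples t on the per-image differences, two-sided p from
    Student's t with n-1 degrees of freedom."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("xs and ys must be 1-D sequences of equal length")
    if x.size < 2:
        raise InputError("need at least two paired observations")
    d = x - y
    if np.allclose(d.var(ddof=1), 0):
        raise DegenerateTestError("paired t-test undefined: zero-variance differences")
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p)
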