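"""Generalized Dice loss for class-imbalanced pixel classification.

With vessels occupying ~9% of a fundus image, plain cross-entropy or
unweighted Dice is dominated by background. The generalized Dice loss
weights each class by the squared inverse of its reference volume,

    GDL = 1 - 2 * (sum_l w_l sum_n r_ln p_ln) / (sum_l w_l sum_n (r_ln + p_ln)),
    w_l = 1 / (sum_n r_ln)^2,

so both classes contribute comparably regardless of pixel counts. The loss
lies in [0, 1], is 0 exactly at perfect one-hot agreement, and is invariant
to duplicating all pixels (class-balanced multiplicity). A class absent
from the reference would give an infinite weight; its weight is replaced
by a large finite cap.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InputError

__all__ = ["generalized_dice_loss", "gdl_and_grad", "dice_coefficient"]

_DEFAULT_CAP = 1e8


def _flatten(reference, probabilities):
    r = np.asarray(reference, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if r.shape != p.shape:
        raise InputError(f"reference and probabilities shapes differ: {r.shape} vs {p.shape}")
    if r.ndim < 2:
        raise InputError("inputs must be (..., n_classes)")
    return r.reshape(-1, r.shape[-1]), p.reshape(-1, p.shape[-1])


def _class_weights(r, cap):
    vol = r.sum(axis=0)
    with np.errstate(divide="ignore"):
        w = 1.0 / vol ** 2
    w[~np.isfinite(w)] = cap
    return np.minimum(w, cap)


def generalized_dice_loss(reference, probabilities, *, absent_class_cap=_DEFAULT_CAP,
                          tol=1e-4, validate=True) -> float:
    """GDL over pixels; inputs are (..., n_classes) with classes last.

    ``reference`` must be one-hot; ``probabilities`` rows must sum to 1
    within ``tol`` (validation error otherwise).
    """
    r, p = _flatten(reference, probabilities)
    if r.shape[0] < 1:
        raise InputError("at least one pixel required")
    if validate:
        if not np.all((r == 0) | (r == 1)) or not np.allclose(r.sum(axis=1), 1):
            raise InputError("reference must be one-hot per pixel")
        if np.any(p < -tol) or np.any(p > 1 + tol):
            raise InputError("probabilities must lie in [0, 1]")
        if not np.all(np.abs(p.sum(axis=1) - 1) <= tol):
            raise InputError("probability rows must sum to 1")
    loss, _ = _gdl(r, p, absent_class_cap)
    return loss


def gdl_and_grad(r, p, absent_class_cap=_DEFAULT_CAP):
    """Unvalidated fast path for training: returns (loss, dL/dp) with the
    same shape as ``p``."""
    shape = np.asarray(p).shape
    r2 = np.asarray(r, dtype=np.float64).reshape(-1, shape[-1])
    p2 = np.asarray(p, dtype=np.float64).reshape(-1, shape[-1])
    loss, grad = _gdl(r2, p2, absent_class_cap, with_grad=True)
    return loss, grad.reshape(shape)


def _gdl(r, p, cap, with_grad=False):
    w = _class_weights(r, cap)
    a = float((w * (r * p).sum(axis=0)).sum())
    b = float((w * (r + p).sum(axis=0)).sum())
    loss = 1.0 - 2.0 * a / b
    if not with_grad:
        return loss, None
    grad = 2.0 * w * (a - r * b) / b ** 2
    return loss, grad


def dice_coefficient(pred_mask, ref_mask) -> float:
    """Plain binary Dice overlap 2|P∩R| / (|P|+|R|); 1.0 when both empty."""
    p = np.asarray(pred_mask).astype(bool)
    r = np.asarray(ref_mask).astype(bool)
    if p.shape != r.shape:
        raise InputError(f"mask shapes differ: {p.shape} vs {r.shape}")
    denom = p.sum() + r.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(p, r).sum() / denom
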