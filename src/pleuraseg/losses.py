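"""Segmentation losses: soft Dice, the anatomical-location penalty, and their sum.

The penalty term is the core of constrained training: for a probability map Y
and a binary admissible-region mask C it is

    P(Y, C) = 1 - |Y ∩ C| / |Y|

with the intersection and size taken as probability mass (soft counts), so the
term is differentiable in Y. P is zero exactly when every unit of predicted
mass lies inside C, and approaches one as the prediction leaves the admissible
region entirely. An all-ones C is the "no constraint" fallback: the penalty
short-circuits to exactly 0 (not merely epsilon-close), so a sample whose
constraint was rejected contributes precisely the unconstrained loss.

All functions accept a single map (H, W) and provide analytic gradients with
respect to the prediction; the training loop consumes the gradient functions
directly.
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError, ShapeMismatchError

EPS = 1e-7


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"shape mismatch: {a.shape} vs {b.shape}")


def _check_binary(mask: np.ndarray) -> None:
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ParameterError("constraint", "mask must be binary (0/1)")


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = EPS) -> float:
    """Soft Dice loss 1 - (2 Σ p·t + ε) / (Σ p + Σ t + ε)."""
    _check_shapes(pred, target)
    inter = float((pred * target).sum())
    denom = float(pred.sum()) + float(target.sum())
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def dice_loss_grad(pred: np.ndarray, target: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Analytic d(dice_loss)/d(pred), same shape as pred."""
    _check_shapes(pred, target)
    inter = float((pred * target).sum())
    denom = float(pred.sum()) + float(target.sum()) + eps
    num = 2.0 * inter + eps
    # quotient rule on (2I+eps)/(S+eps): dI/dp = t, dS/dp = 1
    return -((2.0 * target) * denom - num) / (denom * denom)


def penalty(pred: np.ndarray, constraint: np.ndarray, eps: float = EPS) -> float:
    """Location penalty 1 - Σ(p·c) / (Σ p + ε); exactly 0 for an all-ones c.

    The all-ones short circuit makes the "nullified constraint" fallback exact:
    rejected constraints contribute neither loss nor gradient. An (almost)
    empty prediction also yields 0 — there is no mass to penalize.
    """
    _check_shapes(pred, constraint)
    _check_binary(constraint)
    if constraint.all():
        return 0.0
    total = float(pred.sum())
    if total < eps:
        return 0.0
    inside = float((pred * constraint).sum())
    return 1.0 - inside / (total + eps)


def penalty_grad(pred: np.ndarray, constraint: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Analytic d(penalty)/d(pred); zero on the short-circuit branches."""
    _check_shapes(pred, constraint)
    _check_binary(constraint)
    if constraint.all():
        return np.zeros_like(pred, dtype=np.float64)
    total = float(pred.sum())
    if total < eps:
        return np.zeros_like(pred, dtype=np.float64)
    inside = float((pred * constraint).sum())
    denom = total + eps
    return -(constraint * denom - inside) / (denom * denom)


def constrained_loss(
    preds: np.ndarray,
    targets: np.ndarray,
    constraints: np.ndarray | None,
    lam: float,
) -> float:
    """Batch loss: mean over samples of dice_loss + λ · penalty.

    ``constraints=None`` or λ=0 reduces exactly to the unconstrained baseline
    (mean Dice loss).
    """
    if lam < 0:
        raise ParameterError("lambda_penalty", "must be non-negative")
    if preds.shape != targets.shape:
        raise ShapeMismatchError(f"preds {preds.shape} vs targets {targets.shape}")
    if constraints is not None and constraints.shape != preds.shape:
        raise ShapeMismatchError(f"preds {preds.shape} vs constraints {constraints.shape}")
    n = preds.shape[0]
    total = 0.0
    for i in range(n):
        loss = dice_loss(preds[i], targets[i])
        if constraints is not None and lam > 0:
            c = constraints[i]
            if not c.all():  # all-ones short circuit: skip entirely
                loss += lam * penalty(preds[i], c)
        total += loss
    return total / n


def constrained_loss_grad(
    preds: np.ndarray,
    targets: np.ndarray,
    constraints: np.ndarray | None,
    lam: float,
) -> tuple[float, np.ndarray]:
    """(loss, d loss / d preds) for a batch; gradient shape equals preds."""
    if lam < 0:
        raise ParameterError("lambda_penalty", "must be non-negative")
    n = preds.shape[0]
    grad = np.zeros(preds.shape, dtype=np.float64)
    total = 0.0
    for i in range(n):
        loss = dice_loss(preds[i], targets[i])
        g = dice_loss_grad(preds[i], targets[i])
        if constraints is not None and lam > 0:
            c = constraints[i]
            if not c.all():
                loss += lam * penalty(preds[i], c)
                g = g + lam * penalty_grad(preds[i], c)
        total += loss
        grad[i] = g
    return total / n, grad / n


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; foreground where pred ≥ threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold", "must lie in [0, 1]")
    return pred >= threshold
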