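"""Loss functions returning (scalar loss, gradient w.r.t. prediction)."""

from __future__ import annotations

import numpy as np

_EPS_CLIP = 1e-7


def soft_dice_loss(pred: np.ndarray, target: np.ndarray,
                   smooth: float = 1.0) -> float:
    """Negative soft Dice coefficient, averaged over the batch.

    ``loss = -(2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)`` per sample;
    range [-1, 0] for predictions in [0, 1].
    """
    loss, _ = soft_dice_loss_grad(pred, target, smooth)
    return loss


def soft_dice_loss_grad(pred: np.ndarray, target: np.ndarray,
                        smooth: float = 1.0) -> tuple[float, np.ndarray]:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = pred.reshape(pred.shape[0], -1).astype(np.float64)
    t = target.reshape(target.shape[0], -1).astype(np.float64)
    inter = (p * t).sum(axis=1)
    sums = p.sum(axis=1) + t.sum(axis=1)
    num = 2.0 * inter + smooth
    den = sums + smooth
    per_sample = -num / den
    loss = float(per_sample.mean())
    # d/dp_i of -(2 inter + s)/(den) = -(2 t_i * den - num) / den^2
    grad = -(2.0 * t * den[:, None] - num[:, None]) / (den[:, None] ** 2)
    grad /= pred.shape[0]
    return loss, grad.reshape(pred.shape).astype(np.float32)


def bce_loss_grad(prob: np.ndarray, label: float | np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy on probabilities (post-sigmoid), mean-reduced."""
    p = np.clip(prob.astype(np.float64), _EPS_CLIP, 1.0 - _EPS_CLIP)
    y = np.broadcast_to(np.asarray(label, dtype=np.float64), p.shape)
    loss = float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).mean())
    grad = ((p - y) / (p * (1.0 - p))) / p.size
    return loss, grad.astype(np.float32)
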