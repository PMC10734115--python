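"""Shared training objectives: least-squares adversarial, L1, Dice + CE."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, as_tensor
from .layers import one_hot

__all__ = [
    "lsgan_loss",
    "l1_loss",
    "softmax_cross_entropy",
    "soft_dice_loss",
    "dice_ce_loss",
]


def lsgan_loss(d_out: Tensor, is_real: bool) -> Tensor:
    """Least-squares GAN objective: mean (D(x) - label)^2, label 1 real / 0 fake."""
    d_out = as_tensor(d_out)
    if not np.all(np.isfinite(d_out.data)):
        raise ValueError("discriminator output contains non-finite values")
    target = 1.0 if is_real else 0.0
    return ((d_out - target) ** 2).mean()


def l1_loss(a: Tensor, b: Tensor) -> Tensor:
    return (as_tensor(a) - as_tensor(b)).abs().mean()


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Numerically stable per-pixel mean CE from logits (N,C,H,W) and integer labels (N,H,W)."""
    n, c, h, w = logits.shape
    _check_labels(labels, c)
    x = logits.data
    m = x.max(axis=1, keepdims=True)
    lse = m + np.log(np.exp(x - m).sum(axis=1, keepdims=True))
    logp = x - lse
    oh = one_hot(labels, c)
    val = -(oh * logp).sum() / (n * h * w)
    p = np.exp(logp)

    def backward(g):
        return (g * (p - oh) / (n * h * w),)

    return Tensor._from_op(np.float32(val), (logits,), backward)


def soft_dice_loss(probs: Tensor, labels: np.ndarray, eps: float = 1e-5) -> Tensor:
    """1 - mean soft Dice over classes; probs (N,C,H,W) sum to 1 along C."""
    c = probs.shape[1]
    _check_labels(labels, c)
    oh = Tensor(one_hot(labels, c))
    inter = (probs * oh).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + oh.sum(axis=(0, 2, 3))
    dice = (inter * 2.0 + eps) / (denom + eps)
    return 1.0 - dice.mean()


def dice_ce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Hybrid segmentation loss: soft Dice + cross-entropy."""
    return soft_dice_loss(logits.softmax(axis=1), labels) + softmax_cross_entropy(logits, labels)


def _check_labels(labels: np.ndarray, n_classes: int):
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"label values must lie in [0, {n_classes - 1}], got range "
            f"[{labels.min()}, {labels.max()}]"
        )
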