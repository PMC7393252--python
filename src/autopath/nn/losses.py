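"""Segmentation loss: voxel-wise cross-entropy plus soft Dice, equal weights."""

from __future__ import annotations

import numpy as np


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SegmentationLoss:
    """CE + soft-Dice over 2-class voxel logits.

    ``__call__`` returns (loss_value, grad_wrt_logits). Targets are binary
    (B, D, H, W) arrays; logits are (B, 2, D, H, W). The Dice term is computed
    per sample on the foreground probability and averaged over the batch.
    """

    def __init__(self, dice_eps: float = 1.0):
        self.dice_eps = dice_eps

    def __call__(self, logits: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
        b = logits.shape[0]
        n_vox = int(np.prod(target.shape[1:]))
        t = target.astype(np.float64)
        p = softmax(logits.astype(np.float64), axis=1)
        p1 = p[:, 1]
        p1c = np.clip(p1, 1e-12, 1.0 - 1e-12)

        ce = -(t * np.log(p1c) + (1.0 - t) * np.log(1.0 - p1c)).mean()
        # d ce / d p1, averaged over all voxels
        gce_p1 = (-(t / p1c) + (1.0 - t) / (1.0 - p1c)) / (b * n_vox)

        eps = self.dice_eps
        inter = (p1 * t).sum(axis=(1, 2, 3))
        denom = p1.sum(axis=(1, 2, 3)) + t.sum(axis=(1, 2, 3)) + eps
        dice = (2.0 * inter + eps) / denom
        dice_loss = 1.0 - dice.mean()
        # d dice_i / d p1_i = (2 t - dice) / denom, per sample
        gd = -(2.0 * t - dice[:, None, None, None]) / denom[:, None, None, None] / b

        g_p1 = gce_p1 + gd
        # chain through 2-class softmax: dp1/dz1 = p1(1-p1), dp1/dz0 = -p1(1-p1)
        jac = p1 * (1.0 - p1)
        grad = np.zeros_like(logits, dtype=np.float64)
        grad[:, 1] = g_p1 * jac
        grad[:, 0] = -g_p1 * jac
        return float(ce + dice_loss), grad.astype(np.float32)
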