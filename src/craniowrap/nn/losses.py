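"""Compound Dice + cross-entropy loss for two-channel logits."""

from __future__ import annotations

import numpy as np


def softmax_fg(logits: np.ndarray) -> np.ndarray:
    """Head-channel probability from (D, H, W, 2) logits."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e[..., 0] / e.sum(axis=-1)


def dice_ce_loss(logits: np.ndarray, target: np.ndarray, eps: float = 1e-6):
    """Soft-Dice (foreground channel) plus voxel-mean cross-entropy.

    Parameters
    ----------
    logits
        (D, H, W, 2); channel 0 is the head (foreground).
    target
        (D, H, W) in {0, 1}, 1 = head.

    Returns
    -------
    loss : float
    dlogits : ndarray
        Gradient of the loss w.r.t. the logits.
    """
    t = target.astype(logits.dtype)
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    n = t.size

    p_fg = p[..., 0]
    p_bg = p[..., 1]
    ce = -(t * np.log(p_fg + eps) + (1 - t) * np.log(p_bg + eps)).sum() / n

    inter = (p_fg * t).sum()
    denom = p_fg.sum() + t.sum() + eps
    dice = 2.0 * inter / denom
    loss = ce + (1.0 - dice)

    dp = np.empty_like(p)
    dp[..., 0] = -t / (p_fg + eps) / n \
        - (2.0 * t * denom - 2.0 * inter) / denom ** 2
    dp[..., 1] = -(1 - t) / (p_bg + eps) / n
    # chain through softmax
    s = (dp * p).sum(axis=-1, keepdims=True)
    dlogits = p * (dp - s)
    return float(loss), dlogits.astype(logits.dtype)
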