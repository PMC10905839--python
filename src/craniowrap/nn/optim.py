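"""AdamW with decoupled weight decay and a pluggable learning-rate schedule."""

from __future__ import annotations

import numpy as np


class AdamW:
    """AdamW (default betas 0.9/0.999) with decoupled weight decay.

    ``lr`` may be a float or a callable ``step -> lr`` (the linearly
    decaying schedule used for training passes a callable).
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=1e-5):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        return float(self.lr(self.t) if callable(self.lr) else self.lr)

    def step(self):
        lr = self.current_lr()
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps)
                            + self.wd * p.data)
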