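"""3D attention U-Net for head/background segmentation.

Encoder-decoder with five encoder and four decoder resolution levels,
3^3 convolutions, ReLU activations, dropout inside each double-conv
block, instance normalisation, average-pool downsampling, and
nearest-neighbour upsampling followed by a 3^3 convolution (the
"upsample kernel").  Skip connections pass through additive attention
gates (1^3 convs on gating + skip, ReLU, 1^3 conv, sigmoid) before
concatenation, so the decoder can suppress background context --
the standard attention-gated U-Net construction.

The network maps an (N, N, N) volume (or (N, N, N, 1) tensor) to
(N, N, N, 2) logits (head and background channels).
"""

from __future__ import annotations

import numpy as np

from .layers import (AvgPool2, Conv3d, Dropout, InstanceNorm, Layer, Param,
                     ReLU, Sigmoid, UpsampleNearest2)


class ConvBlock(Layer):
    """conv-norm-relu-dropout-conv-norm-relu."""

    def __init__(self, cin, cout, k, dropout, rng, dtype):
        self.ops = [Conv3d(cin, cout, k, rng, dtype), InstanceNorm(cout, dtype=dtype),
                    ReLU(), Dropout(dropout, rng),
                    Conv3d(cout, cout, k, rng, dtype), InstanceNorm(cout, dtype=dtype),
                    ReLU()]

    def params(self):
        return [p for op in self.ops for p in op.params()]

    def forward(self, x, train=False):
        for op in self.ops:
            x = op.forward(x, train)
        return x

    def backward(self, g):
        for op in reversed(self.ops):
            g = op.backward(g)
        return g


class AttentionGate(Layer):
    """Additive attention on a skip connection.

    ``alpha = sigmoid(psi(relu(Wx x + Wg g)))``; the gated skip is
    ``x * alpha``.  ``x`` is the encoder feature map, ``g`` the decoder
    gating signal at the same resolution.
    """

    def __init__(self, cx, cg, cint, rng, dtype):
        self.wx = Conv3d(cx, cint, 1, rng, dtype)
        self.wg = Conv3d(cg, cint, 1, rng, dtype)
        self.psi = Conv3d(cint, 1, 1, rng, dtype)
        self.relu = ReLU()
        self.sig = Sigmoid()
        self._cache = None

    def params(self):
        return self.wx.params() + self.wg.params() + self.psi.params()

    def forward(self, x, g, train=False):
        a = self.relu.forward(self.wx.forward(x) + self.wg.forward(g))
        alpha = self.sig.forward(self.psi.forward(a))
        self._cache = (x, alpha)
        return x * alpha

    def backward(self, dout):
        x, alpha = self._cache
        dalpha = (dout * x).sum(axis=-1, keepdims=True)
        dx_direct = dout * alpha
        da = self.psi.backward(self.sig.backward(dalpha))
        da = self.relu.backward(da)
        dx = dx_direct + self.wx.backward(da)
        dg = self.wg.backward(da)
        return dx, dg


class AttentionUNet3D:
    """Attention-gated 3D U-Net (see module docstring).

    Parameters
    ----------
    channels
        Output channels per encoder level, shallow to deep
        (clinical-scale reference: ``(32, 64, 128, 256, 512)``).
    in_channels, out_channels
        1 (T2w volume) and 2 (head, background).
    kernel_size, up_kernel_size, dropout
        Convolution kernel, post-upsample kernel, dropout ratio.
    seed
        Initialisation and dropout seed; two builds with the same seed
        have identical parameters.
    """

    def __init__(self, channels=(32, 64, 128, 256, 512), in_channels=1,
                 out_channels=2, kernel_size=3, up_kernel_size=3,
                 dropout=0.5, seed=0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.channels = tuple(channels)
        self.levels = len(channels)
        k, uk = kernel_size, up_kernel_size
        self.enc = []
        cin = in_channels
        for c in channels:
            self.enc.append(ConvBlock(cin, c, k, dropout, rng, dtype))
            cin = c
        self.pools = [AvgPool2() for _ in range(self.levels - 1)]
        self.ups, self.upconvs, self.gates, self.dec = [], [], [], []
        for lvl in range(self.levels - 2, -1, -1):
            c_skip, c_deep = channels[lvl], channels[lvl + 1]
            self.ups.append(UpsampleNearest2())
            self.upconvs.append(Conv3d(c_deep, c_skip, uk, rng, dtype))
            self.gates.append(AttentionGate(c_skip, c_skip,
                                            max(1, c_skip // 2), rng, dtype))
            self.dec.append(ConvBlock(2 * c_skip, c_skip, k, dropout, rng, dtype))
        self.head = Conv3d(channels[0], out_channels, 1, rng, dtype)
        # the image gradient is never consumed
        self.enc[0].ops[0].skip_input_grad = True
        self.dtype = dtype

    # -- parameter plumbing ----------------------------------------------
    def modules(self):
        return (self.enc + self.pools + self.ups + self.upconvs + self.gates
                + self.dec + [self.head])

    def params(self):
        return [p for m in self.modules() for p in m.params()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0

    def state_dict(self):
        return [p.data.copy() for p in self.params()]

    def load_state_dict(self, state):
        for p, d in zip(self.params(), state):
            p.data[...] = d

    # -- forward / backward ----------------------------------------------
    def _check_input(self, x):
        div = 2 ** (self.levels - 1)
        if any(s % div for s in x.shape[:3]):
            raise ValueError(
                f"input size {x.shape[:3]} not divisible by {div} "
                f"(required by {self.levels} resolution levels)")

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        self._check_input(x)
        skips = []
        for lvl in range(self.levels):
            x = self.enc[lvl].forward(x, train)
            if lvl < self.levels - 1:
                skips.append(x)
                x = self.pools[lvl].forward(x, train)
        self._skip_channels = []
        for i, lvl in enumerate(range(self.levels - 2, -1, -1)):
            x = self.ups[i].forward(x, train)
            x = self.upconvs[i].forward(x, train)
            gated = self.gates[i].forward(skips[lvl], x, train)
            self._skip_channels.append(gated.shape[-1])
            x = np.concatenate([gated, x], axis=-1)
            x = self.dec[i].forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits):
        g = self.head.backward(dlogits.astype(self.dtype))
        dskips = {}
        for i in range(len(self.dec) - 1, -1, -1):
            lvl = self.levels - 2 - i
            g = self.dec[i].backward(g)
            c = self._skip_channels[i]
            dgated, dup = g[..., :c], g[..., c:]
            dskip, dg_gate = self.gates[i].backward(dgated)
            dskips[lvl] = dskip
            g = self.upconvs[i].backward(dup + dg_gate)
            g = self.ups[i].backward(g)
        for lvl in range(self.levels - 1, -1, -1):
            if lvl < self.levels - 1:
                g = self.pools[lvl].backward(g)
                g = g + dskips[lvl]
            g = self.enc[lvl].backward(g)
        return g
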