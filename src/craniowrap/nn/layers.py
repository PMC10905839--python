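"""Layers with explicit forward/backward over (D, H, W, C) tensors.

Channel-last layout: a spatial shift of the zero-padded, flattened
volume is then a contiguous row slice, so each of the k^3 kernel taps of
a convolution reduces to one contiguous (voxels x Cin) @ (Cin x Cout)
matmul.  The tap loop runs inside a z-slab loop sized so the
accumulator, input slab and matmul temporary stay cache-resident; this
is what makes CPU training of the desk-scale U-Net practical.

All state lives in :class:`Param` objects (value + accumulated
gradient).  Tensors are single volumes; the training loop runs batch
size 1.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = data
        self.grad = np.zeros_like(data)


class Layer:
    def params(self):
        return []


def _pad_cl(x: np.ndarray, p: int) -> np.ndarray:
    D, H, W, C = x.shape
    xp = np.zeros((D + 2 * p, H + 2 * p, W + 2 * p, C), x.dtype)
    xp[p:D + p, p:H + p, p:W + p] = x
    return xp


def _slab_for(ci: int) -> int:
    # keep accumulator + temporaries cache-resident while amortising the
    # python-level tap loop for very thin layers
    return 8 if ci <= 4 else 4 if ci <= 16 else 2


def conv3d_forward(x: np.ndarray, w: np.ndarray,
                   slab: int | None = None) -> np.ndarray:
    """Same-padded stride-1 convolution; x (D,H,W,Ci), w (k,k,k,Ci,Co)."""
    k = w.shape[0]
    if k == 1:
        return x @ w[0, 0, 0]
    p = k // 2
    D, H, W, Ci = x.shape
    Co = w.shape[-1]
    if slab is None:
        slab = _slab_for(Ci)
    Hp, Wp = H + 2 * p, W + 2 * p
    xp = _pad_cl(x, p)
    out = np.empty((D, H, W, Co), x.dtype)
    offs = [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]
    for z0 in range(0, D, slab):
        z1 = min(z0 + slab, D)
        M = (z1 - z0) * Hp * Wp
        acc = None
        for dz, dy, dx in offs:
            shift = (dy - p) * Wp + (dx - p)
            src = xp[z0 + dz:z1 + dz].reshape(-1, Ci)
            wk = w[dz, dy, dx]
            if acc is None:
                acc = np.zeros((M, Co), x.dtype)
            if shift >= 0:
                acc[:M - shift] += src[shift:] @ wk
            else:
                acc[-shift:] += src[:M + shift] @ wk
        out[z0:z1] = acc.reshape(z1 - z0, Hp, Wp, Co)[:, p:Hp - p, p:Wp - p]
    return out


def conv3d_wgrad(x: np.ndarray, g: np.ndarray, k: int,
                 slab: int | None = None) -> np.ndarray:
    """Kernel gradient: dw[tap] = sum over voxels x[.+tap] (x) g[.]."""
    Ci = x.shape[-1]
    Co = g.shape[-1]
    if k == 1:
        return (x.reshape(-1, Ci).T @ g.reshape(-1, Co))[None, None, None]
    p = k // 2
    D, H, W = x.shape[:3]
    if slab is None:
        slab = _slab_for(Ci)
    Hp, Wp = H + 2 * p, W + 2 * p
    xp = _pad_cl(x, p)
    gp = _pad_cl(g, p)  # zero padding kills out-of-range contributions
    dw = np.zeros((k, k, k, Ci, Co), np.float64)
    offs = [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]
    for z0 in range(0, D, slab):
        z1 = min(z0 + slab, D)
        gf = gp[z0 + p:z1 + p].reshape(-1, Co)
        M = gf.shape[0]
        for dz, dy, dx in offs:
            shift = (dy - p) * Wp + (dx - p)
            src = xp[z0 + dz:z1 + dz].reshape(-1, Ci)
            if shift >= 0:
                dw[dz, dy, dx] += src[shift:].T @ gf[:M - shift]
            else:
                dw[dz, dy, dx] += src[:M + shift].T @ gf[-shift:]
    return dw.astype(x.dtype)


def conv3d_backward(x: np.ndarray, g: np.ndarray, w: np.ndarray,
                    need_dx: bool = True, slab: int | None = None):
    """Fused backward for a same-padded stride-1 conv.

    Returns ``(dw, dx)``.  One slab sweep touches the padded input and
    padded output-gradient once for both contractions: ``dw[tap]``
    accumulates ``x[.+tap] (x) g[.]`` and ``dx`` accumulates the full
    correlation of ``g`` with the flipped, channel-transposed kernel
    (realised per tap as ``g[.-tap] @ w[tap].T``).
    """
    k = w.shape[0]
    Ci, Co = w.shape[3], w.shape[4]
    if k == 1:
        dw = (x.reshape(-1, Ci).T @ g.reshape(-1, Co))[None, None, None]
        dx = (g @ w[0, 0, 0].T) if need_dx else None
        return dw, dx
    p = k // 2
    D, H, W = x.shape[:3]
    if slab is None:
        slab = _slab_for(Ci)
    Hp, Wp = H + 2 * p, W + 2 * p
    xp = _pad_cl(x, p)
    gp = _pad_cl(g, p)
    dw = np.zeros((k, k, k, Ci, Co), np.float64)
    dx = np.empty((D, H, W, Ci), x.dtype) if need_dx else None
    offs = [(a, b, c) for a in range(k) for b in range(k) for c in range(k)]
    for z0 in range(0, D, slab):
        z1 = min(z0 + slab, D)
        gslab = gp[z0 + p:z1 + p].reshape(-1, Co)
        M = gslab.shape[0]
        acc = np.zeros((M, Ci), x.dtype) if need_dx else None
        for dz, dy, dx_ in offs:
            shift = (dy - p) * Wp + (dx_ - p)
            src = xp[z0 + dz:z1 + dz].reshape(-1, Ci)
            wk = w[dz, dy, dx_]
            # dx at voxel v needs g[v - tap]: g slab planes z0+p-(dz-p)
            gsrc = gp[z0 + 2 * p - dz:z1 + 2 * p - dz].reshape(-1, Co)
            if shift >= 0:
                dw[dz, dy, dx_] += src[shift:].T @ gslab[:M - shift]
                if need_dx:
                    acc[shift:] += gsrc[:M - shift] @ wk.T
            else:
                dw[dz, dy, dx_] += src[:M + shift].T @ gslab[-shift:]
                if need_dx:
                    acc[:M + shift] += gsrc[-shift:] @ wk.T
        if need_dx:
            dx[z0:z1] = acc.reshape(z1 - z0, Hp, Wp, Ci)[:, p:Hp - p,
                                                         p:Wp - p]
    return dw, dx


class Conv3d(Layer):
    """k^3 same-padded convolution with bias, He-initialised."""

    def __init__(self, cin, cout, k=3, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k ** 3))
        self.k = k
        self.w = Param((rng.standard_normal((k, k, k, cin, cout)) * std)
                       .astype(dtype))
        self.b = Param(np.zeros(cout, dtype=dtype))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        return conv3d_forward(x, self.w.data) + self.b.data

    def backward(self, g):
        need_dx = not getattr(self, "skip_input_grad", False)
        dw, dx = conv3d_backward(self._x, g, self.w.data, need_dx=need_dx)
        self.w.grad += dw.astype(self.w.grad.dtype)
        self.b.grad += g.reshape(-1, g.shape[-1]).sum(axis=0)
        return dx


class InstanceNorm(Layer):
    """Per-channel normalisation over the spatial axes, with affine."""

    def __init__(self, c, eps=1e-5, dtype=np.float32):
        self.eps = eps
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        xf = x.reshape(-1, x.shape[-1])
        n = xf.shape[0]
        s1 = np.einsum("nc->c", xf, dtype=np.float64)
        s2 = np.einsum("nc,nc->c", xf, xf, dtype=np.float64)
        mu = s1 / n
        var = np.maximum(s2 / n - mu * mu, 0.0)
        inv = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mu.astype(x.dtype)) * inv
        self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, g):
        xhat, inv = self._cache
        c = g.shape[-1]
        gf = g.reshape(-1, c)
        xf = xhat.reshape(-1, c)
        n = gf.shape[0]
        s1 = np.einsum("nc->c", gf, dtype=np.float64)
        s2 = np.einsum("nc,nc->c", gf, xf, dtype=np.float64)
        self.gamma.grad += s2.astype(self.gamma.grad.dtype)
        self.beta.grad += s1.astype(self.beta.grad.dtype)
        gam = self.gamma.data
        m1 = (gam * s1 / n).astype(g.dtype)
        m2 = (gam * s2 / n).astype(g.dtype)
        out = g * gam
        out -= m1
        out -= xhat * m2
        out *= inv
        return out


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        if g.base is None and g.flags.writeable:
            np.multiply(g, self._mask, out=g)
            return g
        return g * self._mask


class Sigmoid(Layer):
    def forward(self, x, train=False):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p, rng=None):
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng()
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p <= 0:
            self._mask = None
            return x
        keep = np.float32(1.0 - self.p)
        u = self.rng.random(x.shape, dtype=np.float32)
        self._mask = (u < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g):
        if self._mask is None:
            return g
        if g.base is None and g.flags.writeable:
            np.multiply(g, self._mask, out=g)
            return g
        return g * self._mask


class AvgPool2(Layer):
    """2x2x2 average pooling (requires even spatial dims)."""

    def forward(self, x, train=False):
        d, h, w, c = x.shape
        return x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(1, 3, 5))

    def backward(self, g):
        up = np.repeat(np.repeat(np.repeat(g, 2, 0), 2, 1), 2, 2)
        return (up / g.dtype.type(8.0))


class UpsampleNearest2(Layer):
    def forward(self, x, train=False):
        return np.repeat(np.repeat(np.repeat(x, 2, 0), 2, 1), 2, 2)

    def backward(self, g):
        d, h, w, c = g.shape
        return g.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(1, 3, 5))
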