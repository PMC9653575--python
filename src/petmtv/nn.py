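"""A compact CPU neural-network engine for 2-D segmentation.

Implements exactly the layers the residual U-Net needs — 3x3 (optionally
dilated) convolution, batch normalization, ReLU, 2x2 max pooling, bilinear
x2 upsampling, channel concatenation and residual addition — with explicit
hand-written backward passes, plus a softmax cross-entropy + soft-Dice loss
and an Adam optimizer with L2 weight decay. Everything is float32 numpy;
convolutions are evaluated as im2col matrix products so the heavy lifting
runs through BLAS. All randomness flows through an explicit
``numpy.random.Generator``, so training is reproducible bit-for-bit.

Layout convention: activations are ``(N, C, H, W)`` float32 arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "BilinearUp2",
    "ResidualBlock",
    "Adam",
    "softmax",
    "ce_dice_loss_and_grad",
]

F32 = np.float32


class Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("data", "grad", "m", "v", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)
        self.m = np.zeros_like(self.data)
        self.v = np.zeros_like(self.data)
        self.name = name


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _shift_conv(x: np.ndarray, w: np.ndarray, dilation: int) -> np.ndarray:
    """Stride-1 'same' convolution of (N,C,H,W) with (O,C,k,k) weights.

    Evaluated as k*k shifted matrix products over a padded transposed view,
    which keeps all heavy work inside BLAS without im2col materialization.
    Returns (N,H,W,O) -- note the channels-last output layout.
    """
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    if k == 1:
        return np.matmul(x.transpose(0, 2, 3, 1), w[:, :, 0, 0].T)
    pad = dilation * (k // 2)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    xt = xp.transpose(0, 2, 3, 1)  # (N, H+2p, W+2p, C) view
    out = np.zeros((n, h, wd, o), dtype=F32)
    for i in range(k):
        for j in range(k):
            v = xt[:, i * dilation:i * dilation + h, j * dilation:j * dilation + wd, :]
            out += v @ w[:, :, i, j].T
    return out


class Conv2d(Layer):
    """Stride-1 'same' convolution with odd kernel and optional dilation."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        assert k % 2 == 1, "kernel size must be odd"
        rng = rng if rng is not None else np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))  # He initialization for ReLU nets
        self.w = Param(rng.normal(0.0, std, (cout, cin, k, k)), f"{name}.w")
        self.b = Param(np.zeros(cout), f"{name}.b") if bias else None
        self.cin, self.cout, self.k, self.dilation = cin, cout, k, dilation
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        out = _shift_conv(x, self.w.data, self.dilation)
        if self.b is not None:
            out += self.b.data
        return out.transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._x is not None
        x, k, dil = self._x, self.k, self.dilation
        n, c, h, wd = x.shape
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # (N,H,W,O)
        if self.b is not None:
            self.b.grad += gt.sum(axis=(0, 1, 2))
        if k == 1:
            gm = gt.reshape(-1, self.cout)
            xm = x.transpose(0, 2, 3, 1).reshape(-1, c)
            self.w.grad[:, :, 0, 0] += gm.T @ xm
            dx = (gm @ self.w.data[:, :, 0, 0]).reshape(n, h, wd, c)
            self._x = None
            return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))
        pad = dil * (k // 2)
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        xt = xp.transpose(0, 2, 3, 1)
        gm = gt.reshape(-1, self.cout)
        for i in range(k):
            for j in range(k):
                v = xt[:, i * dil:i * dil + h, j * dil:j * dil + wd, :]
                vm = np.ascontiguousarray(v).reshape(-1, c)
                self.w.grad[:, :, i, j] += gm.T @ vm
        # dX is the 'same' convolution of g with the spatially flipped,
        # in/out-transposed kernel (valid for stride 1, odd k, same padding).
        wt = np.ascontiguousarray(
            self.w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        dx = _shift_conv(g, wt, dil)
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=np.float64)
            var = x.var(axis=(0, 2, 3), dtype=np.float64)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        mean = np.asarray(mean, dtype=F32)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        if train:
            self._cache = (xhat, invstd, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._cache is not None
        xhat, invstd, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gxhat = g * self.gamma.data[None, :, None, None]
        s1 = gxhat.sum(axis=(0, 2, 3))
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3))
        dx = (invstd[None, :, None, None] / m) * (
            m * gxhat
            - s1[None, :, None, None]
            - xhat * s2[None, :, None, None]
        )
        self._cache = None
        return dx.astype(F32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        dx = g * self._mask
        self._mask = None
        return dx


# ---------------------------------------------------------------------------
# Resampling layers
# ---------------------------------------------------------------------------

class MaxPool2(Layer):
    """2x2 max pooling with stride 2; requires even H and W."""

    def __init__(self) -> None:
        self._argmax: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "MaxPool2 needs even spatial size"
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        if train:
            self._argmax = xr.argmax(axis=-1)
            self._shape = x.shape
        return xr.max(axis=-1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._argmax is not None and self._shape is not None
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(out, self._argmax[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._argmax = None
        return np.ascontiguousarray(out.reshape(n, c, h, w))


def _bilinear_matrix(n_in: int) -> np.ndarray:
    """(2*n_in, n_in) interpolation matrix for x2 bilinear upsampling.

    Uses the half-pixel-centre mapping src = (dst + 0.5)/2 - 0.5 with edge
    clamping, i.e. the standard align_corners=False convention.
    """
    n_out = 2 * n_in
    m = np.zeros((n_out, n_in), dtype=F32)
    for d in range(n_out):
        s = (d + 0.5) / 2.0 - 0.5
        s = min(max(s, 0.0), n_in - 1.0)
        i0 = int(np.floor(s))
        i1 = min(i0 + 1, n_in - 1)
        frac = s - i0
        m[d, i0] += 1.0 - frac
        m[d, i1] += frac
    return m


class BilinearUp2(Layer):
    """x2 bilinear upsampling, implemented as separable matrix products."""

    def __init__(self) -> None:
        self._mats: dict[int, np.ndarray] = {}
        self._shape: tuple[int, ...] | None = None

    def _mat(self, n_in: int) -> np.ndarray:
        if n_in not in self._mats:
            self._mats[n_in] = _bilinear_matrix(n_in)
        return self._mats[n_in]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if train:
            self._shape = x.shape
        mh, mw = self._mat(h), self._mat(w)
        out = np.einsum("oh,nchw->ncow", mh, x, optimize=True)
        out = np.einsum("pw,ncow->ncop", mw, out, optimize=True)
        return np.ascontiguousarray(out, dtype=F32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        assert self._shape is not None
        n, c, h, w = self._shape
        mh, mw = self._mat(h), self._mat(w)
        dx = np.einsum("oh,ncop->nchp", mh, g, optimize=True)
        dx = np.einsum("pw,nchp->nchw", mw, dx, optimize=True)
        self._shape = None
        return np.ascontiguousarray(dx, dtype=F32)


# ---------------------------------------------------------------------------
# Residual block
# ---------------------------------------------------------------------------

class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn plus a (projected) shortcut, then ReLU.

    The shortcut is the identity when input and output channel counts agree
    and a 1x1 convolution + batch norm otherwise.
    """

    def __init__(self, cin: int, cout: int, dilation: int = 1,
                 batch_norm: bool = True, rng: np.random.Generator | None = None,
                 name: str = "res") -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.conv1 = Conv2d(cin, cout, 3, dilation, rng=rng, name=f"{name}.conv1")
        self.conv2 = Conv2d(cout, cout, 3, dilation, rng=rng, name=f"{name}.conv2")
        self.bn1 = BatchNorm2d(cout, name=f"{name}.bn1") if batch_norm else None
        self.bn2 = BatchNorm2d(cout, name=f"{name}.bn2") if batch_norm else None
        self.relu1, self.relu_out = ReLU(), ReLU()
        if cin != cout:
            self.proj: Conv2d | None = Conv2d(cin, cout, 1, rng=rng, name=f"{name}.proj")
            self.proj_bn = BatchNorm2d(cout, name=f"{name}.proj_bn") if batch_norm else None
        else:
            self.proj, self.proj_bn = None, None

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in (self.conv1, self.bn1, self.conv2, self.bn2, self.proj, self.proj_bn):
            if layer is not None:
                out += layer.params()
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.conv1.forward(x, train)
        if self.bn1 is not None:
            h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        if self.bn2 is not None:
            h = self.bn2.forward(h, train)
        if self.proj is not None:
            s = self.proj.forward(x, train)
            if self.proj_bn is not None:
                s = self.proj_bn.forward(s, train)
        else:
            s = x
        return self.relu_out.forward(h + s, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(g)
        gs = g
        if self.proj_bn is not None:
            gs = self.proj_bn.backward(gs)
        if self.proj is not None:
            gx_short = self.proj.backward(gs)
        else:
            gx_short = gs
        gh = g
        if self.bn2 is not None:
            gh = self.bn2.backward(gh)
        gh = self.conv2.backward(gh)
        gh = self.relu1.backward(gh)
        if self.bn1 is not None:
            gh = self.bn1.backward(gh)
        gx_main = self.conv1.backward(gh)
        return gx_main + gx_short


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def ce_dice_loss_and_grad(
    logits: np.ndarray,
    targets: np.ndarray,
    weight: float = 0.5,
    smooth: float = 1.0,
) -> tuple[float, float, float, np.ndarray]:
    """Combined loss ``w*CE + (1-w)*(1 - mean soft-Dice over foreground)``.

    ``logits`` is (N,C,H,W); ``targets`` is (N,H,W) integer class labels.
    Class 0 is background and excluded from the Dice average. Soft Dice for
    class c uses batch-global sums: (2*I_c + s) / (P_c + T_c + s).

    Returns (total, ce, dice_loss, dlogits).
    """
    n, c, h, w = logits.shape
    p = softmax(np.asarray(logits, dtype=F32), axis=1)
    onehot = np.zeros_like(p)
    idx = np.indices((n, h, w))
    onehot[idx[0], targets, idx[1], idx[2]] = 1.0

    npix = n * h * w
    pt = p[idx[0], targets, idx[1], idx[2]]
    ce = float(-np.log(np.maximum(pt, 1e-12)).mean(dtype=np.float64))
    dlogits = (p - onehot) * F32(weight / npix)

    # Soft Dice over the foreground classes PRESENT in the batch (sums in
    # float64). Classes absent from the batch are excluded: their Dice term
    # would otherwise exert a large uniform push toward zero probability --
    # orders of magnitude stronger per pixel than the cross-entropy -- and
    # whichever classes happen to be under-sampled early in training never
    # recover. Cross-entropy alone penalizes their false positives.
    fg = slice(1, c)
    inter = (p[:, fg] * onehot[:, fg]).sum(axis=(0, 2, 3), dtype=np.float64)
    psum = p[:, fg].sum(axis=(0, 2, 3), dtype=np.float64)
    tsum = onehot[:, fg].sum(axis=(0, 2, 3), dtype=np.float64)
    present = tsum > 0
    n_present = int(present.sum())
    if n_present == 0:
        total = weight * ce
        return total, ce, 0.0, dlogits.astype(F32)
    denom = psum + tsum + smooth
    dice = (2.0 * inter + smooth) / denom
    dice_loss = float(1.0 - dice[present].mean())

    # d(dice_c)/d(p_c) = (2*t_c*D - (2*I_c+s)) / D^2, then chain through softmax
    ddice_dp = np.zeros_like(p)
    ddice_dp[:, fg] = (2.0 * onehot[:, fg] * denom[None, :, None, None]
                       - (2.0 * inter + smooth)[None, :, None, None]).astype(F32) \
        / (denom ** 2).astype(F32)[None, :, None, None]
    ddice_dp[:, fg] *= present[None, :, None, None]
    dl_dp = F32(-(1.0 - weight) / n_present) * ddice_dp
    # softmax Jacobian: dL/dz = p * (dL/dp - sum_c dL/dp_c * p_c)
    dot = (dl_dp * p).sum(axis=1, keepdims=True)
    dlogits += p * (dl_dp - dot)

    total = weight * ce + (1.0 - weight) * dice_loss
    return total, ce, dice_loss, dlogits.astype(F32)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with classic L2 weight decay added to the gradient."""

    def __init__(self, params: list[Param], lr: float = 3e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 1e-4) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p in self.params:
            g = p.grad
            if self.weight_decay and p.data.ndim > 1:  # decay conv kernels only
                g = g + self.weight_decay * p.data
            p.m[...] = b1 * p.m + (1 - b1) * g
            p.v[...] = b2 * p.v + (1 - b2) * (g * g)
            mhat = p.m / bias1
            vhat = p.v / bias2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(F32)
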