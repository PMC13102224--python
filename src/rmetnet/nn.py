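"""Neural-network building blocks on the autodiff engine.

Stride-1 2-D convolutions (full and depthwise), linear layers, layer/batch
normalisation, dropout, average pooling and the Adam optimiser with the
max-norm kernel constraint used throughout the decoder.  Convolutions are
implemented as strided-window ``einsum`` contractions with hand-written
vector-Jacobian products; everything else composes autodiff primitives.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Conv2d",
    "DepthwiseConv1d",
    "Linear",
    "LayerNorm",
    "BatchNorm",
    "Dropout",
    "avg_pool_last",
    "softmax",
    "apply_maxnorm",
    "Adam",
]


class Parameter(Tensor):
    """Trainable tensor; ``constrain=True`` marks max-norm-capped kernels."""

    __slots__ = ("constrain",)

    def __init__(self, data, constrain: bool = False):
        super().__init__(data, requires_grad=True)
        self.constrain = constrain


class Module:
    """Minimal container: tracks sub-modules/parameters by attribute name."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _windows(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    b, c, h, w = x.shape
    sb, sc, sh, sw = x.strides
    return as_strided(
        x,
        shape=(b, c, h - kh + 1, w - kw + 1, kh, kw),
        strides=(sb, sc, sh, sw, sh, sw),
        writeable=False,
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, padding=(0, 0), depthwise=False) -> Tensor:
    """Stride-1 cross-correlation.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, kh, kw) or (C, 1, kh, kw) when
    ``depthwise`` (then Cout = Cin = C).  ``padding`` is symmetric-ish zero
    padding (ph, pw) given as (left == top) amounts; for even kernels the
    extra pad sample goes to the right, matching "same" conventions.
    """
    ph, pw = padding
    if not isinstance(ph, tuple):
        ph, pw = (ph, ph), (pw, pw)
    kh, kw = w.shape[-2:]
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph[0], ph[1]), (pw[0], pw[1])))
    bsz, cin, hp, wp = xp.shape
    ho, wo = hp - kh + 1, wp - kw + 1
    parents = (x, w) if b is None else (x, w, b)

    if depthwise:
        # tap loop: k is small, each tap is a vectorised multiply-add
        wd = w.data[:, 0]  # (C, kh, kw); kh == 1 in practice but keep general
        out = np.zeros((bsz, cin, ho, wo))
        for i in range(kh):
            for j in range(kw):
                out += wd[:, i, j][None, :, None, None] * xp[:, :, i : i + ho, j : j + wo]
        if b is not None:
            out = out + b.data[None, :, None, None]

        def backward(g):
            gw = np.empty_like(wd)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    patch = xp[:, :, i : i + ho, j : j + wo]
                    gw[:, i, j] = np.einsum("bchw,bchw->c", g, patch, optimize=True)
                    gxp[:, :, i : i + ho, j : j + wo] += (
                        wd[:, i, j][None, :, None, None] * g
                    )
            gx = gxp[:, :, ph[0] : ph[0] + x.shape[2], pw[0] : pw[0] + x.shape[3]]
            if b is None:
                return gx, gw[:, None]
            return gx, gw[:, None], g.sum(axis=(0, 2, 3))

        return Tensor._from_op(out, parents, backward)

    # im2col + BLAS matmul in channels-last layout; the column matrix is
    # cached for the backward pass and the input gradient is folded back by
    # a short loop over kernel taps (contiguous destination slices)
    cout = w.shape[0]
    xcl = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (b, hp, wp, cin)
    s0, s1, s2, s3 = xcl.strides
    win = as_strided(
        xcl,
        shape=(bsz, ho, wo, kh, kw, cin),
        strides=(s0, s1, s2, s1, s2, s3),
        writeable=False,
    )
    col = np.ascontiguousarray(win).reshape(bsz * ho * wo, kh * kw * cin)
    wmat = np.ascontiguousarray(w.data.transpose(2, 3, 1, 0)).reshape(kh * kw * cin, cout)
    out = (col @ wmat).reshape(bsz, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(bsz * ho * wo, cout)
        gw = (col.T @ gmat).reshape(kh, kw, cin, cout).transpose(3, 2, 0, 1)
        gcl = (gmat @ wmat.T).reshape(bsz, ho, wo, kh, kw, cin)
        gxp = np.zeros_like(xcl)
        for i in range(kh):
            for j in range(kw):
                gxp[:, i : i + ho, j : j + wo, :] += gcl[:, :, :, i, j, :]
        gx = gxp[:, ph[0] : ph[0] + x.shape[2], pw[0] : pw[0] + x.shape[3], :]
        gx = gx.transpose(0, 3, 1, 2)
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor._from_op(out, parents, backward)


def _same_pad(k: int) -> tuple[int, int]:
    # total k-1, extra sample on the right for even kernels
    return ((k - 1) // 2, k // 2)


class Conv2d(Module):
    """Full-channel-mixing stride-1 convolution with optional same padding."""

    def __init__(self, in_ch, out_ch, kernel, padding="valid", rng=None, constrain=True):
        super().__init__()
        kh, kw = kernel
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kh * kw
        scale = np.sqrt(1.0 / fan_in)
        self.weight = Parameter(rng.uniform(-scale, scale, (out_ch, in_ch, kh, kw)), constrain=constrain)
        self.bias = Parameter(np.zeros(out_ch))
        self.padding = (_same_pad(kh), _same_pad(kw)) if padding == "same" else ((0, 0), (0, 0))

    def __call__(self, x: Tensor) -> Tensor:
        ph, pw = self.padding
        return conv2d(x, self.weight, self.bias, (ph, pw))


class DepthwiseConv1d(Module):
    """Per-channel 1-D convolution along time with same-length output."""

    def __init__(self, channels, kernel, rng=None, constrain=True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / kernel)
        self.weight = Parameter(rng.uniform(-scale, scale, (channels, 1, 1, kernel)), constrain=constrain)
        self.bias = Parameter(np.zeros(channels))
        self.padding = ((0, 0), _same_pad(kernel))

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, C, T) -> treat as (B, C, 1, T)
        y = x.reshape(x.shape[0], x.shape[1], 1, x.shape[2])
        y = conv2d(y, self.weight, self.bias, self.padding, depthwise=True)
        return y.reshape(x.shape[0], x.shape[1], x.shape[2])


class Linear(Module):
    def __init__(self, in_features, out_features, rng=None, constrain=False):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-scale, scale, (out_features, in_features)), constrain=constrain)
        self.bias = Parameter(np.zeros(out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight.transpose(1, 0) + self.bias


class LayerNorm(Module):
    """Normalises over the channel axis (axis 1) of (B, d, T) activations."""

    def __init__(self, dim, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones((1, dim, 1)))
        self.beta = Parameter(np.zeros((1, dim, 1)))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=1, keepdims=True)
        xhat = xc / (var + self.eps) ** 0.5
        return xhat * self.gamma + self.beta


class BatchNorm(Module):
    """Batch normalisation over (B, F, L) per feature map."""

    def __init__(self, num_features, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, num_features, 1)))
        self.beta = Parameter(np.zeros((1, num_features, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, num_features, 1))
        self.running_var = np.ones((1, num_features, 1))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            xc = x - mu
            var = (xc**2).mean(axis=(0, 2), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
        else:
            mu = Tensor(self.running_mean)
            var = Tensor(self.running_var)
            xc = x - mu
        xhat = xc / (var + self.eps) ** 0.5
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None):
        super().__init__()
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


def avg_pool_last(x: Tensor, kernel: int, stride: int) -> Tensor:
    """Average pooling along the last axis; L = floor((W - k)/s) + 1."""
    w = x.shape[-1]
    if kernel > w:
        raise ValueError(f"pool kernel {kernel} exceeds length {w}")
    L = (w - kernel) // stride + 1
    starts = [l * stride for l in range(L)]
    out = np.stack([x.data[..., s : s + kernel].mean(axis=-1) for s in starts], axis=-1)

    def backward(g):
        gx = np.zeros_like(x.data)
        for l, s in enumerate(starts):
            gx[..., s : s + kernel] += g[..., l, None] / kernel
        return (gx,)

    return Tensor._from_op(out, (x,), backward)


def softmax(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=-1, keepdims=True)


def apply_maxnorm(model: Module, c: float = 2.0) -> Module:
    """Rescale every constrained kernel whose flattened L2 norm exceeds ``c``.

    Direction-preserving, idempotent; unconstrained parameters are untouched.
    Filters are the leading axis of each kernel tensor.
    """
    if c <= 0:
        raise ValueError("maxnorm cap must be positive")
    for p in model.parameters():
        if not getattr(p, "constrain", False):
            continue
        flat = p.data.reshape(p.data.shape[0], -1)
        norms = np.linalg.norm(flat, axis=1, keepdims=True)
        scale = np.where(norms > c, c / np.maximum(norms, 1e-30), 1.0)
        p.data = (flat * scale).reshape(p.data.shape)
    return model


class Adam:
    """Adam with additive L2 weight decay (decay added to the raw gradient)."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
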