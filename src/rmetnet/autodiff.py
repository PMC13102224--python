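"""Reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine: each :class:`Tensor` wraps an ``ndarray`` and
records the operation that produced it.  Calling :meth:`Tensor.backward`
topologically sorts the tape and accumulates vector-Jacobian products into
``.grad``.  Only the primitives the decoder architecture needs are provided
(elementwise arithmetic, matmul, reductions, shape ops, GELU/ReLU, clamping
and a straight-through threshold gate); convolutions and pooling are built on
top of these in :mod:`rmetnet.nn`.

Everything is double precision and deterministic: identical inputs produce
bit-identical outputs and gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "ste_mask"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _from_op(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._from_op(out_data, (self, other), backward)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def gelu(self):
        # exact (erf-based) GELU
        from scipy.special import erf

        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)

        def backward(g):
            return (g * (cdf + x * pdf),)

        return Tensor._from_op(x * cdf, (self,), backward)

    def clamp_min(self, lo: float):
        mask = self.data >= lo

        def backward(g):
            return (g * mask,)

        return Tensor._from_op(np.maximum(self.data, lo), (self,), backward)

    # -- reductions and shape ops -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._from_op(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        def backward(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, idx, g)
            return (gi,)

        return Tensor._from_op(self.data[idx], (self,), backward)

    def pad_last(self, left: int, right: int):
        """Zero-pad the last axis."""
        width = [(0, 0)] * (self.ndim - 1) + [(left, right)]
        n = self.shape[-1]

        def backward(g):
            sl = [slice(None)] * (self.ndim - 1) + [slice(left, left + n)]
            return (g[tuple(sl)],)

        return Tensor._from_op(np.pad(self.data, width), (self,), backward)

    # -- autodiff driver ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def concat(tensors, axis=0):
    tensors = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tuple(tensors), backward)


def ste_mask(p_norm: Tensor, theta: Tensor, tau: float = 0.02) -> Tensor:
    """Hard binary mask ``p_norm > theta`` with a straight-through gradient.

    Forward emits the exact indicator used for spectral thresholding; the
    backward pass substitutes the derivative of a sigmoid surrogate of width
    ``tau``, which is what makes the threshold trainable at all (the hard
    indicator has zero gradient almost everywhere).
    """
    p_norm = Tensor.as_tensor(p_norm)
    theta = Tensor.as_tensor(theta)
    hard = (p_norm.data > theta.data).astype(np.float64)
    z = (p_norm.data - theta.data) / tau
    sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    dsig = sig * (1.0 - sig) / tau

    def backward(g):
        return (
            _unbroadcast(g * dsig, p_norm.shape),
            _unbroadcast(-g * dsig, theta.shape),
        )

    return Tensor._from_op(hard, (p_norm, theta), backward)
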