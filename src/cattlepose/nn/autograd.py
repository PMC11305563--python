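"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains and evaluates small convolutional pose networks on CPU;
this module supplies exactly the tensor operations those networks need
(convolution via im2col, batch normalization, pooling, nearest upsampling,
pointwise nonlinearities, concatenation/slicing and reductions), each with an
analytic backward pass.  Arrays follow the NCHW layout throughout.

Gradients are accumulated by a topological sweep over the recorded graph;
graph recording is disabled inside :func:`no_grad` (used for inference and
profiling).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to the reflected operators below instead of building
    # object arrays when an ndarray meets a Tensor
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._parents: tuple = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, processed = stack.pop()
                if processed:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` down to ``shape`` (reverse numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.astype(np.float32, copy=False)


# -- elementwise -------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a, eps: float = 1e-12) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(np.maximum(a.data, eps))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / np.maximum(a.data, eps))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    z = np.clip(a.data, -60.0, 60.0)  # saturated logistic, overflow-safe
    out_data = (1.0 / (1.0 + np.exp(-z))).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def silu(a) -> Tensor:
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out_data = a.data * s

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data.astype(np.float32), (a,), backward)


def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if a.requires_grad:
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - dot))

    return _make(out_data, (a,), backward)


# -- reductions & shaping ----------------------------------------------------

def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.shape).astype(np.float32))

    return _make(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.transpose(inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

    return _make(out_data, (a,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, tuple(tensors), backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * as_tensor(a).ndim
    sl[axis] = slice(start, start + length)
    return getitem(a, tuple(sl))


# -- convolution et al. ------------------------------------------------------

def _windows(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    w = sliding_window_view(xp, (k, k), axis=(2, 3))
    return w[:, :, ::stride, ::stride, :, :]


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW, square kernel."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, wdt = x.shape
    cout, cin_g, k, _ = weight.shape
    if cin % groups or cout % groups:
        raise ValueError("channels not divisible by groups")
    if cin_g != cin // groups:
        raise ValueError(
            f"weight expects {cin_g * groups} input channels, got {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    win = _windows(xp, k, stride)  # N, Cin, Ho, Wo, k, k
    ho, wo = win.shape[2], win.shape[3]
    if groups == 1:
        out_data = np.einsum("ocij,nchwij->nohw", weight.data, win, optimize=True)
    else:
        out_data = np.empty((n, cout, ho, wo), dtype=np.float32)
        cg, og = cin // groups, cout // groups
        for g_i in range(groups):
            out_data[:, g_i * og:(g_i + 1) * og] = np.einsum(
                "ocij,nchwij->nohw",
                weight.data[g_i * og:(g_i + 1) * og],
                win[:, g_i * cg:(g_i + 1) * cg], optimize=True)
    if bias is not None:
        bias = as_tensor(bias)
        out_data = out_data + bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        cg, og = cin // groups, cout // groups
        if weight.requires_grad:
            if groups == 1:
                dw = np.einsum("nohw,nchwij->ocij", g, win, optimize=True)
            else:
                dw = np.empty_like(weight.data)
                for g_i in range(groups):
                    dw[g_i * og:(g_i + 1) * og] = np.einsum(
                        "nohw,nchwij->ocij", g[:, g_i * og:(g_i + 1) * og],
                        win[:, g_i * cg:(g_i + 1) * cg], optimize=True)
            weight._accumulate(dw)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            if groups == 1:
                gcol = np.einsum("nohw,ocij->nchwij", g, weight.data, optimize=True)
            else:
                gcol = np.empty(win.shape, dtype=np.float32)
                for g_i in range(groups):
                    gcol[:, g_i * cg:(g_i + 1) * cg] = np.einsum(
                        "nohw,ocij->nchwij", g[:, g_i * og:(g_i + 1) * og],
                        weight.data[g_i * og:(g_i + 1) * og], optimize=True)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + stride * ho:stride,
                        j:j + stride * wo:stride] += gcol[..., i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return _make(out_data.astype(np.float32), parents, backward)


def conv_transpose2d(x, weight, bias=None, stride: int = 2) -> Tensor:
    """Transposed convolution with kernel size == stride (non-overlapping),
    the learned x2 upsampler used in the neck.  weight: (Cin, Cout, k, k)."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, cin, h, w = x.shape
    cin_w, cout, k, _ = weight.shape
    if cin_w != cin:
        raise ValueError("channel mismatch")
    if k != stride:
        raise ValueError("only kernel_size == stride supported")
    out_data = np.zeros((n, cout, h * k, w * k), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            out_data[:, :, i::k, j::k] = np.einsum(
                "nchw,co->nohw", x.data, weight.data[:, :, i, j], optimize=True)
    if bias is not None:
        bias = as_tensor(bias)
        out_data += bias.data[None, :, None, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            dw = np.empty_like(weight.data)
            for i in range(k):
                for j in range(k):
                    dw[:, :, i, j] = np.einsum(
                        "nchw,nohw->co", x.data, g[:, :, i::k, j::k], optimize=True)
            weight._accumulate(dw)
        if x.requires_grad:
            dx = np.zeros_like(x.data)
            for i in range(k):
                for j in range(k):
                    dx += np.einsum("nohw,co->nchw", g[:, :, i::k, j::k],
                                    weight.data[:, :, i, j], optimize=True)
            x._accumulate(dx)

    return _make(out_data, parents, backward)


def maxpool2d(x, kernel_size: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    win = _windows(xp, kernel_size, stride)
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, kernel_size * kernel_size)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        ii, jj = np.divmod(idx, kernel_size)
        nn_, cc, hh, ww = np.indices(idx.shape)
        np.add.at(dxp, (nn_, cc, hh * stride + ii, ww * stride + jj), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    return _make(out_data.astype(np.float32), (x,), backward)


def upsample_nearest2(x) -> Tensor:
    """Nearest-neighbour x2 spatial upsampling."""
    x = as_tensor(x)
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x._accumulate(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def batchnorm2d(x, gamma, beta, running_mean, running_var, training: bool,
                momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    In training mode batch statistics are used and running statistics are
    updated in place; in inference mode the running statistics are used.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        cnt = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= (1 - momentum)
        running_mean += momentum * m
        running_var *= (1 - momentum)
        running_var += momentum * v * (cnt / max(cnt - 1, 1))
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
            if training:
                nhw = g.shape[0] * g.shape[2] * g.shape[3]
                gsum = g.sum(axis=(0, 2, 3), keepdims=False)[None, :, None, None]
                gxsum = (g * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
                dx = gi * (g - gsum / nhw - xhat * gxsum / nhw)
            else:
                dx = gi * g
            x._accumulate(dx.astype(np.float32))

    return _make(out_data.astype(np.float32), (x, gamma, beta), backward)
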