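"""Reverse-mode automatic differentiation over numpy arrays.

A small tensor engine sufficient for convolutional/transformer segmentation
models on CPU: elementwise ops with broadcasting, (batched) matmul,
reductions, 2-D convolution via im2col, 2x2 max pooling, and deterministic
x2 bilinear upsampling.  Gradients are accumulated by a topological sweep;
``no_grad`` disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True) if g.dtype != self.data.dtype else g.copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph eagerly
                node._parents = ()
                node._backward = None
                if not node.requires_grad or node is not self:
                    pass

    # -- convenience ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- elementwise arithmetic -------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bw(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return Tensor._make(out_data, (a,), bw)

    # -- transcendental ----------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bw)

    def tanh(self):
        a = self
        t = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - t * t))

        return Tensor._make(t, (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bw)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient flows only through the interior."""
        a = self
        mask = (a.data > lo) & (a.data < hi)

        def bw(g):
            a._accum(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), bw)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                grad = np.broadcast_to(g, a.data.shape)
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
                grad = np.broadcast_to(g, a.data.shape)
            a._accum(np.ascontiguousarray(grad))

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        mx = a.data.max(axis=axis, keepdims=True)
        mask = a.data == mx

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            counts = mask.sum(axis=axis, keepdims=True)
            a._accum(g * mask / counts)

        return Tensor._make(mx if keepdims else mx.squeeze(axis), (a,), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def bw(g):
            a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = tuple(np.argsort(axes))

        def bw(g):
            a._accum(np.ascontiguousarray(g.transpose(inv)))

        return Tensor._make(np.ascontiguousarray(a.data.transpose(axes)), (a,), bw)

    def __matmul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = g @ b.data.swapaxes(-1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = a.data.swapaxes(-1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(a.data @ b.data, (a, b), bw)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.ascontiguousarray(p))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax; the max shift is treated as a constant."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- convolution ----------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int):
    b, c, h, w = xp.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (b, c, kh, kw, oh, ow), (s0, s1, s2, s3, s2 * stride, s3 * stride)
    )
    return np.ascontiguousarray(view).reshape(b, c * kh * kw, oh * ow), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (B,C,H,W), w: (Co,C,kh,kw), b: (Co,)."""
    co, ci, kh, kw = w.data.shape
    if x.data.shape[1] != ci:
        raise ValueError(f"conv2d channel mismatch: input {x.data.shape} vs weight {w.data.shape}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    cols, oh, ow = _im2col(xp, kh, kw, stride)
    wm = w.data.reshape(co, -1)
    out = wm @ cols  # (B, Co, L) via broadcasting of (Co,K)@(B,K,L)
    if b is not None:
        out = out + b.data.reshape(1, co, 1)
    out = out.reshape(x.data.shape[0], co, oh, ow)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gr = g.reshape(g.shape[0], co, oh * ow)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("bol,bkl->ok", gr, cols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = (wm.T @ gr).reshape(g.shape[0], ci, kh, kw, oh, ow)
            hp, wp = xp.shape[2], xp.shape[3]
            dx = np.zeros((g.shape[0], ci, hp, wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcols[:, :, i, j]
            if padding:
                dx = dx[:, :, padding:hp - padding, padding:wp - padding]
            x._accum(dx)

    return Tensor._make(out, parents, bw)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gx = np.zeros_like(xr)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        gx = gx.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        x._accum(gx)

    return Tensor._make(out, (x,), bw)


@lru_cache(maxsize=64)
def _bilinear_matrix(n_in: int) -> np.ndarray:
    """(2n x n) interpolation matrix for x2 bilinear upsampling (half-pixel centers)."""
    a = np.zeros((2 * n_in, n_in))
    for i in range(2 * n_in):
        src = min(max((i + 0.5) / 2.0 - 0.5, 0.0), n_in - 1.0)
        f = int(np.floor(src))
        c = min(f + 1, n_in - 1)
        t = src - f
        a[i, f] += 1.0 - t
        a[i, c] += t
    return a


def upsample2x_bilinear(x: Tensor) -> Tensor:
    """Deterministic x2 bilinear upsampling of (B,C,H,W)."""
    b, c, h, w = x.data.shape
    ah = _bilinear_matrix(h).astype(x.data.dtype)
    aw = _bilinear_matrix(w).astype(x.data.dtype)
    out = np.einsum("hp,bcpq,wq->bchw", ah, x.data, aw, optimize=True)

    def bw(g):
        x._accum(np.einsum("hp,bchw,wq->bcpq", ah, g, aw, optimize=True))

    return Tensor._make(out, (x,), bw)
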