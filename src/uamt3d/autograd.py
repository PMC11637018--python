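"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations an encoder-decoder 3D CNN needs: elementwise
arithmetic with broadcasting, matmul, 3D convolution (stride 1, "same"
padding), 2x max pooling, nearest-neighbour 2x upsampling, channel
concatenation, dropout, reductions, and the usual activations.  Tensors wrap
numpy arrays; gradients are accumulated by a topological backward sweep.

Convolution is implemented as im2col + matmul, which is the fastest route a
pure-numpy backend has on one CPU.  Every backward pass here is covered by a
central-difference gradient check in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "no_grad", "add", "sub", "mul", "div", "matmul", "log", "exp",
    "sqrt", "square", "tsum", "sigmoid", "leaky_relu", "relu", "conv3d",
    "maxpool2", "upsample_nearest2", "concat", "dropout", "narrow",
    "spatial_max", "channel_max", "reshape", "softmax",
]

_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference / EMA)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False
        return self

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        arr = np.asarray(data)
        if arr.dtype.kind in "iub":
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None
        self.name = name

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other, self))

    def __radd__(self, other):
        return add(_as_tensor(other, self), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other, self))

    def __rsub__(self, other):
        return sub(_as_tensor(other, self), self)

    def __mul__(self, other):
        return mul(self, _as_tensor(other, self))

    def __rmul__(self, other):
        return mul(_as_tensor(other, self), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other, self))

    def __rtruediv__(self, other):
        return div(_as_tensor(other, self), self)

    def __neg__(self):
        return mul(self, _as_tensor(-1.0, self))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in ax]))
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- backward ------------------------------------------------------
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and (p.requires_grad or p._backward is not None):
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not (parent.requires_grad or parent._backward is not None):
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def _as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else np.float32
    return Tensor(np.asarray(x, dtype=dtype))


def _make(data, parents, backward) -> Tensor:
    track = _GRAD_ENABLED[0] and any(
        p.requires_grad or p._backward is not None for p in parents
    )
    out = Tensor(data)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


# -- elementwise arithmetic ---------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data - b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.data.shape),
                            _unbroadcast(g * a.data, b.data.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data / b.data, (a, b),
                 lambda g: (_unbroadcast(g / b.data, a.data.shape),
                            _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)))


def log(a: Tensor) -> Tensor:
    return _make(np.log(a.data), (a,), lambda g: (g / a.data,))


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    return _make(out, (a,), lambda g: (g * out,))


def sqrt(a: Tensor) -> Tensor:
    out = np.sqrt(a.data)
    return _make(out, (a,), lambda g: (g * (0.5 / out),))


def square(a: Tensor) -> Tensor:
    return _make(a.data * a.data, (a,), lambda g: (g * (2.0 * a.data),))


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).astype(a.data.dtype),)
        gg = g
        if not keepdims:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            gg = np.expand_dims(g, ax)
        return (np.broadcast_to(gg, a.data.shape).astype(a.data.dtype),)

    return _make(out, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data @ b.data, (a, b),
                 lambda g: (g @ b.data.T, a.data.T @ g))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


# -- activations ---------------------------------------------------------

def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data))
    return _make(out, (a,), lambda g: (g * out * (1.0 - out),))


def leaky_relu(a: Tensor, alpha: float = 0.01) -> Tensor:
    mask = a.data > 0
    out = np.where(mask, a.data, alpha * a.data)
    return _make(out, (a,), lambda g: (np.where(mask, g, alpha * g),))


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return _make(np.where(mask, a.data, 0.0), (a,),
                 lambda g: (np.where(mask, g, 0.0),))


# -- convolution ---------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """'Same' 3D convolution, stride 1, odd cubic kernel.

    x: (C_in, D, H, W); w: (C_out, C_in, k, k, k); b: (C_out,) or None.
    """
    cin, D, H, W = x.data.shape
    cout, cin_w, k, _, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin_w}")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
    cols = sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    cols = np.ascontiguousarray(cols.transpose(1, 2, 3, 0, 4, 5, 6))
    cols = cols.reshape(D * H * W, cin * k ** 3)
    wmat = w.data.reshape(cout, cin * k ** 3)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = np.ascontiguousarray(out.T).reshape(cout, D, H, W)

    def backward(g):
        gm = np.ascontiguousarray(g.reshape(cout, -1).T)  # (V, cout)
        gw = (gm.T @ cols).reshape(w.data.shape)
        gb = g.sum(axis=(1, 2, 3)) if b is not None else None
        gcols = gm @ wmat  # (V, cin*k^3)
        gc = gcols.reshape(D, H, W, cin, k, k, k)
        gxp = np.zeros_like(xp)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    gxp[:, a:a + D, bb:bb + H, c:c + W] += \
                        gc[:, :, :, :, a, bb, c].transpose(3, 0, 1, 2)
        gx = gxp[:, p:p + D, p:p + H, p:p + W]
        return (gx, gw, gb) if b is not None else (gx, gw)

    parents = (x, w, b) if b is not None else (x, w)
    return _make(out, parents, backward)


# -- pooling / resampling -------------------------------------------------

def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; all spatial dims must be even."""
    C, D, H, W = x.data.shape
    if D % 2 or H % 2 or W % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {(D, H, W)}")
    win = x.data.reshape(C, D // 2, 2, H // 2, 2, W // 2, 2)
    win = np.ascontiguousarray(win.transpose(0, 1, 3, 5, 2, 4, 6))
    win = win.reshape(C, D // 2, H // 2, W // 2, 8)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros((C, D // 2, H // 2, W // 2, 8), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(C, D // 2, H // 2, W // 2, 2, 2, 2)
        gw = gw.transpose(0, 1, 4, 2, 5, 3, 6).reshape(C, D, H, W)
        return (gw,)

    return _make(out, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling along the three spatial axes."""
    out = x.data.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        C, D, H, W = x.data.shape
        gg = g.reshape(C, D, 2, H, 2, W, 2).sum(axis=(2, 4, 6))
        return (gg,)

    return _make(out, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out, tuple(tensors), backward)


def narrow(x: Tensor, axis: int, start: int, length: int) -> Tensor:
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)

    def backward(g):
        gx = np.zeros_like(x.data)
        gx[sl] = g
        return (gx,)

    return _make(x.data[sl], (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; caller decides whether the layer is active."""
    if not 0.0 <= p < 1.0:
        raise ValueError("dropout rate must be in [0,1)")
    if p == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return _make(x.data * mask, (x,), lambda g: (g * mask,))


# -- reductions used by attention ----------------------------------------

def spatial_max(x: Tensor) -> Tensor:
    """Global max over the spatial axes of a (C, D, H, W) map -> (C,)."""
    C = x.data.shape[0]
    flat = x.data.reshape(C, -1)
    idx = flat.argmax(axis=1)
    out = flat[np.arange(C), idx]

    def backward(g):
        gf = np.zeros_like(flat)
        gf[np.arange(C), idx] = g
        return (gf.reshape(x.data.shape),)

    return _make(out, (x,), backward)


def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis of a (C, D, H, W) map -> (1, D, H, W)."""
    idx = x.data.argmax(axis=0)
    out = np.take_along_axis(x.data, idx[None], axis=0)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx[None], g, axis=0)
        return (gx,)

    return _make(out, (x,), backward)


def softmax(x: Tensor, axis: int = 0) -> Tensor:
    """Numerically stable softmax (shift by a detached max)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = exp(sub(x, shift))
    return div(e, tsum(e, axis=axis, keepdims=True))
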