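"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the prognosis networks need: broadcasting
arithmetic, (batched) matrix products, pointwise nonlinearities, reductions,
shape surgery and numerically stable softmax / layer-norm / binary
cross-entropy compositions.  Gradients of every composite used by the models
are validated against central finite differences in the test suite.

Graphs are built eagerly and freed after each backward pass; there is no
tape reuse, no in-place mutation of tracked tensors and no implicit global
state.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "backward",
    "concat",
    "conv1d_time",
    "layer_norm",
    "log_sigmoid",
    "softmax",
    "softplus",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._prev: tuple[Tensor, ...] = ()
        self._backward = None

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    # -- operators -------------------------------------------------------
    def __add__(self, other):
        return _add(self, as_tensor(other))

    def __radd__(self, other):
        return _add(as_tensor(other), self)

    def __sub__(self, other):
        return _add(self, _neg(as_tensor(other)))

    def __rsub__(self, other):
        return _add(as_tensor(other), _neg(self))

    def __neg__(self):
        return _neg(self)

    def __mul__(self, other):
        return _mul(self, as_tensor(other))

    def __rmul__(self, other):
        return _mul(as_tensor(other), self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return _mul(self, _pow(other, -1.0))

    def __rtruediv__(self, other):
        return _mul(as_tensor(other), _pow(self, -1.0))

    def __pow__(self, p):
        return _pow(self, float(p))

    def __matmul__(self, other):
        return _matmul(self, as_tensor(other))

    def __getitem__(self, idx):
        return _getitem(self, idx)

    # -- pointwise -------------------------------------------------------
    def exp(self):
        return _exp(self)

    def log(self):
        return _log(self)

    def tanh(self):
        return _tanh(self)

    def sigmoid(self):
        return _sigmoid(self)

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        return _sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return _sum(self, axis, keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return _reshape(self, shape)

    def swapaxes(self, a: int, b: int):
        return _swapaxes(self, a, b)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _axis_size(shape, axis) -> int:
    if isinstance(axis, int):
        return shape[axis]
    n = 1
    for a in axis:
        n *= shape[a]
    return n


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


def _accum(t: Tensor, grad: np.ndarray) -> None:
    if not t.requires_grad and t._backward is None:
        return
    grad = _unbroadcast(np.asarray(grad), t.data.shape)
    t.grad = grad if t.grad is None else t.grad + grad


def _make(data: np.ndarray, prev: Sequence[Tensor], backward_fn) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._backward is not None for p in prev):
        out.requires_grad = True
        out._prev = tuple(prev)
        out._backward = backward_fn
    return out


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g)
        _accum(b, g)

    return _make(a.data + b.data, (a, b), bw)


def _neg(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, -g)

    return _make(-a.data, (a,), bw)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _make(a.data * b.data, (a, b), bw)


def _pow(a: Tensor, p: float) -> Tensor:
    def bw(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _make(a.data ** p, (a,), bw)


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad or a._backward is not None:
            _accum(a, np.matmul(g, b.data.swapaxes(-1, -2)))
        if b.requires_grad or b._backward is not None:
            _accum(b, np.matmul(a.data.swapaxes(-1, -2), g))

    return _make(np.matmul(a.data, b.data), (a, b), bw)


def _exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bw(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), bw)


def _log(a: Tensor) -> Tensor:
    def bw(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), bw)


def _tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def bw(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), bw)


def _sigmoid(a: Tensor) -> Tensor:
    # stable logistic: exp(-|x|) never overflows
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    out_data = out_data.astype(x.dtype, copy=False)

    def bw(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bw)


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)) computed without overflow; d/dx = sigmoid(x)."""
    a = as_tensor(a)
    x = a.data
    out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))

    def bw(g):
        s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
        _accum(a, g * s)

    return _make(out_data, (a,), bw)


def log_sigmoid(a: Tensor) -> Tensor:
    """log σ(x) = −softplus(−x)."""
    return _neg(softplus(_neg(as_tensor(a))))


def _sum(a: Tensor, axis, keepdims: bool) -> Tensor:
    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.data.shape))

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def _reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape

    def bw(g):
        _accum(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), bw)


def _swapaxes(a: Tensor, ax1: int, ax2: int) -> Tensor:
    def bw(g):
        _accum(a, g.swapaxes(ax1, ax2))

    return _make(a.data.swapaxes(ax1, ax2), (a,), bw)


def _getitem(a: Tensor, idx) -> Tensor:
    def bw(g):
        full = np.zeros_like(a.data)
        full[idx] += g
        _accum(a, full)

    return _make(a.data[idx], (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


# ---------------------------------------------------------------------------
# composites
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Softmax with max-subtraction for numerical stability.

    Fused primitive: the Jacobian-vector product is
    y ⊙ (g − ⟨g, y⟩) along the softmax axis.
    """
    x = as_tensor(x)
    e = np.exp(x.data - x.data.max(axis=axis, keepdims=True))
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        _accum(x, y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return _make(y, (x,), bw)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis (fused forward/backward)."""
    x, gain, bias = as_tensor(x), as_tensor(gain), as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gain.data + bias.data

    def bw(g):
        lead = tuple(range(g.ndim - 1))
        _accum(gain, (g * xhat).sum(axis=lead))
        _accum(bias, g.sum(axis=lead))
        if x.requires_grad or x._backward is not None:
            dxhat = g * gain.data
            dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
            _accum(x, dx)

    return _make(out_data, (x, gain, bias), bw)


def conv1d_time(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """'Same'-padded 1-D convolution over the middle (time) axis.

    x: (B, T, C_in); W: (k, C_in, C_out); b: (C_out,).
    y[:, t] = Σ_o x[:, t + o − k//2] @ W[o] + b with zero padding.
    """
    x, W, b = as_tensor(x), as_tensor(W), as_tensor(b)
    B, T, _ = x.data.shape
    k, _, c_out = W.data.shape
    half = k // 2
    y = np.zeros((B, T, c_out), dtype=x.data.dtype)
    for o in range(k):
        s = o - half
        lo, hi = max(0, -s), min(T, T - s)
        y[:, lo:hi] += x.data[:, lo + s:hi + s] @ W.data[o]
    y += b.data

    def bw(g):
        lead = (0, 1)
        _accum(b, g.sum(axis=lead))
        dW = np.zeros_like(W.data)
        need_dx = x.requires_grad or x._backward is not None
        dx = np.zeros_like(x.data) if need_dx else None
        for o in range(k):
            s = o - half
            lo, hi = max(0, -s), min(T, T - s)
            xs = x.data[:, lo + s:hi + s].reshape(-1, x.data.shape[-1])
            gs = g[:, lo:hi].reshape(-1, c_out)
            dW[o] = xs.T @ gs
            if need_dx:
                dx[:, lo + s:hi + s] += (gs @ W.data[o].T).reshape(
                    B, hi - lo, -1)
        _accum(W, dW)
        if need_dx:
            _accum(x, dx)

    return _make(y, (x, W, b), bw)


def backward(root: Tensor, grad: np.ndarray | None = None) -> None:
    """Reverse-mode sweep from `root` (iterative topological order)."""
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._prev:
            if id(p) not in visited:
                stack.append((p, False))

    root.grad = np.ones_like(root.data) if grad is None else np.asarray(grad)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
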