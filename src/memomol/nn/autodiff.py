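"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine provides exactly the operator set needed by the recurrent
memory cells and the character-level CNN in this package: elementwise
arithmetic with broadcasting, matmul (batched), common activations,
reductions, indexing/gather, concatenation, rolls, cumulative products
(for usage-based memory allocation) and 1-D unfolding for convolution.

Design notes
------------
* A :class:`Tensor` wraps an ``np.ndarray`` plus an optional backward
  closure.  Graphs are built eagerly; :meth:`Tensor.backward` runs an
  iterative topological sort (graphs from long unrolled sequences exceed
  the default recursion limit).
* Gradients are only tracked through tensors that require them; wrapping
  plain arrays is cheap, so the same code paths serve both training and
  fast inference.
* dtype follows the inputs.  Gradient-check tests build float64 cells;
  training uses float32 by default.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "parameter",
    "add", "mul", "matmul", "exp", "log", "sqrt", "tanh", "sigmoid",
    "relu", "softplus", "power", "clip_value",
    "tsum", "tmean", "tmax",
    "reshape", "transpose", "concat", "take", "roll", "cumprod",
    "softmax", "log_softmax", "unfold1d", "maxpool1d", "dropout", "no_grad",
    "oneplus",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _bw=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._bw = _bw

    # -- plumbing ----------------------------------------------------
    @property
    def needs_grad(self) -> bool:
        return self.requires_grad or bool(self._parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self._bw is not None})"

    # -- autograd ----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=self.data.dtype)
        # iterative topological order (graphs can be thousands of nodes deep)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.needs_grad:
                    stack.append((p, False))
        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._bw is None:
                continue
            for parent, pg in zip(node._parents, node._bw(g)):
                if pg is None or not parent.needs_grad:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operator sugar ----------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=True)


_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (fast inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _op(data, parents, bw):
    if not _GRAD_ENABLED:
        return Tensor(data)
    parents = tuple(as_tensor(p) for p in parents)
    if any(p.needs_grad for p in parents):
        return Tensor(data, _parents=parents, _bw=bw)
    return Tensor(data)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def bw(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _op(out, (a, b), bw)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def bw(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _op(out, (a, b), bw)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def bw(g):
        ad, bd = a.data, b.data
        if ad.ndim == 1 and bd.ndim == 1:
            return g * bd, g * ad
        if ad.ndim == 1:
            ga = (g[..., None, :] * np.swapaxes(bd, -1, -2)).sum(-1)
            gb = ad[:, None] * g[..., None, :]
        elif bd.ndim == 1:
            ga = g[..., :, None] * bd
            gb = (ad * g[..., :, None]).sum(tuple(range(ad.ndim - 1)))
        else:
            ga = g @ np.swapaxes(bd, -1, -2)
            gb = np.swapaxes(ad, -1, -2) @ g
        return _unbroadcast(ga, ad.shape), _unbroadcast(gb, bd.shape)

    return _op(out, (a, b), bw)


def power(a, p: float):
    a = as_tensor(a)
    out = a.data ** p

    def bw(g):
        return (g * p * a.data ** (p - 1.0),)

    return _op(out, (a,), bw)


def exp(a):
    a = as_tensor(a)
    out = np.exp(a.data)

    def bw(g):
        return (g * out,)

    return _op(out, (a,), bw)


def log(a):
    a = as_tensor(a)
    out = np.log(a.data)

    def bw(g):
        return (g / a.data,)

    return _op(out, (a,), bw)


def sqrt(a):
    return power(a, 0.5)


def tanh(a):
    a = as_tensor(a)
    out = np.tanh(a.data)

    def bw(g):
        return (g * (1.0 - out * out),)

    return _op(out, (a,), bw)


def sigmoid(a):
    a = as_tensor(a)
    out = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def bw(g):
        return (g * out * (1.0 - out),)

    return _op(out, (a,), bw)


def relu(a):
    a = as_tensor(a)
    out = np.maximum(a.data, 0.0)

    def bw(g):
        return (g * (a.data > 0),)

    return _op(out, (a,), bw)


def softplus(a):
    a = as_tensor(a)
    x = a.data
    out = np.logaddexp(0.0, x)

    def bw(g):
        return (g / (1.0 + np.exp(-np.clip(x, -60.0, 60.0))),)

    return _op(out, (a,), bw)


def oneplus(a):
    """1 + softplus(a); squashes onto (1, inf) (sharpening exponents)."""
    return add(softplus(a), 1.0)


def clip_value(a, lo: float, hi: float):
    """Clip with straight-through gradient inside the clipped range."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)

    def bw(g):
        return (g * ((a.data >= lo) & (a.data <= hi)),)

    return _op(out, (a,), bw)


# ---------------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        g = np.asarray(g)
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _op(out, (a,), bw)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tmax(a, axis: int, keepdims=False):
    a = as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out = np.squeeze(out, axis=axis)

    def bw(g):
        g = np.asarray(g)
        if not keepdims:
            g = np.expand_dims(g, axis)
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.expand_dims(idx, axis), g, axis=axis)
        return (ga,)

    return _op(out, (a,), bw)


# ---------------------------------------------------------------------------
# shape / indexing
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    out = a.data.reshape(shape)

    def bw(g):
        return (g.reshape(a.data.shape),)

    return _op(out, (a,), bw)


def transpose(a, axes):
    a = as_tensor(a)
    out = a.data.transpose(axes)
    inv = np.argsort(axes)

    def bw(g):
        return (g.transpose(inv),)

    return _op(out, (a,), bw)


def _idx_is_basic(idx) -> bool:
    """True for pure slice/int indexing (no repeats -> plain += works)."""
    if isinstance(idx, (slice, int)):
        return True
    if isinstance(idx, tuple):
        return all(isinstance(i, (slice, int)) for i in idx)
    return False


def take(a, idx):
    """NumPy basic or integer-array indexing with scatter-add backward."""
    a = as_tensor(a)
    out = a.data[idx]
    basic = _idx_is_basic(idx)

    def bw(g):
        ga = np.zeros_like(a.data)
        if basic:
            ga[idx] += g
        else:
            np.add.at(ga, idx, g)
        return (ga,)

    return _op(out, (a,), bw)


def concat(parts, axis=0):
    parts = [as_tensor(p) for p in parts]
    out = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return _op(out, tuple(parts), bw)


def roll(a, shift: int, axis: int):
    a = as_tensor(a)
    out = np.roll(a.data, shift, axis=axis)

    def bw(g):
        return (np.roll(g, -shift, axis=axis),)

    return _op(out, (a,), bw)


def cumprod(a, axis: int = -1):
    """Cumulative product with a zero-safe O(N) backward recurrence.

    For c_j = prod_{k<=j} u_k the gradient is
    du_i = L_i * T_i with L_i = prod_{k<i} u_k and
    T_i = g_i + u_{i+1} T_{i+1}, avoiding division (safe at u_k = 0).
    """
    a = as_tensor(a)
    u = np.moveaxis(a.data, axis, -1)
    c = np.cumprod(u, axis=-1)
    out = np.moveaxis(c, -1, axis)

    def bw(grad):
        g = np.moveaxis(grad, axis, -1)
        n = u.shape[-1]
        L = np.ones_like(u)
        L[..., 1:] = c[..., :-1]
        T = np.empty_like(u)
        T[..., n - 1] = g[..., n - 1]
        for i in range(n - 2, -1, -1):
            T[..., i] = g[..., i] + u[..., i + 1] * T[..., i + 1]
        return (np.moveaxis(L * T, -1, axis),)

    return _op(out, (a,), bw)


# ---------------------------------------------------------------------------
# softmax family
# ---------------------------------------------------------------------------

def softmax(a, axis=-1):
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _op(out, (a,), bw)


def log_softmax(a, axis=-1):
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def bw(g):
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return _op(out, (a,), bw)


# ---------------------------------------------------------------------------
# convolution helpers
# ---------------------------------------------------------------------------

def unfold1d(a, k: int):
    """(B, L, C) -> (B, L-k+1, k*C) sliding windows for 'valid' conv1d."""
    a = as_tensor(a)
    B, L, C = a.data.shape
    Lo = L - k + 1
    win = np.lib.stride_tricks.sliding_window_view(a.data, Lo, axis=1)
    # win: (B, k, C, Lo) -> (B, Lo, k, C)
    out = win.transpose(0, 3, 1, 2).reshape(B, Lo, k * C)

    def bw(g):
        g = g.reshape(B, Lo, k, C)
        ga = np.zeros_like(a.data)
        for j in range(k):
            ga[:, j:j + Lo, :] += g[:, :, j, :]
        return (ga,)

    return _op(out, (a,), bw)


def maxpool1d(a, p: int):
    """(B, L, C) -> (B, L//p, C), max over non-overlapping windows."""
    a = as_tensor(a)
    B, L, C = a.data.shape
    Lo = L // p
    x = reshape(take(a, (slice(None), slice(0, Lo * p))), (B, Lo, p, C))
    return tmax(x, axis=2)


def dropout(a, rate: float, rng: np.random.Generator):
    """Inverted dropout; pass rate=0 or rng=None for inference."""
    if rate <= 0.0 or rng is None:
        return as_tensor(a)
    a = as_tensor(a)
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, mask.astype(a.data.dtype))
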