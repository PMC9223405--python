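"""Differentiable recurrent cells with external memory.

Three memory-augmented architectures are implemented alongside three
baselines, all sharing one interface so they are drop-in sequence cells:

* **StackRNN** — an LSTM controller coupled to a differentiable
  push-down stack driven by soft push/pop/no-op actions.
* **NTM** — an LSTM controller with an external N x M memory matrix
  addressed by content (cosine similarity) and location (gated
  interpolation, circular shift, sharpening), with erase/add writes.
* **DNC** — the NTM extended with usage-based allocation, a precedence
  vector and a temporal link matrix supporting forward/backward reads.
* **RNN / GRU / LSTM** — memoryless baselines.

The addressing primitives are exposed as standalone functions that
accept either plain NumPy arrays or autodiff tensors (single vectors or
batches); the cells call the same code, so unit tests of the math cover
the training path too.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor, as_tensor
from .nn.optim import ParamStore

ARCHITECTURES = ("rnn", "gru", "lstm", "stackrnn", "ntm", "dnc")

#: order of the soft stack action components
STACK_ACTIONS = ("push", "pop", "noop")

_EPS_COS = 1e-8     # additive guard in cosine-similarity norm product
_EPS_POW = 1e-16    # guard inside w^gamma = exp(gamma*log(w))


@dataclass
class MemoryConfig:
    """Shape of the external memory and controller.

    Defaults mirror the full-scale configuration (200 memory locations,
    1024-wide rows/embeddings/controller); desk-scale experiments
    override them.
    """

    n_locations: int = 200
    word_size: int = 1024
    controller_units: int = 1024
    embedding_length: int = 1024
    n_read_heads: int = 1
    n_write_heads: int = 1

    def __post_init__(self):
        for name in ("n_locations", "word_size", "controller_units",
                     "embedding_length", "n_read_heads", "n_write_heads"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# generic helpers: every addressing op accepts arrays or tensors,
# batched (leading axis) or single
# ---------------------------------------------------------------------------

def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _tensor_mode(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def _promote(x, nd: int) -> Tensor:
    """Ensure a leading batch axis so inputs of rank nd-1 work too."""
    t = as_tensor(x)
    if t.data.ndim == nd - 1:
        t = ad.reshape(t, (1,) + t.data.shape)
    return t


def _finish(out: Tensor, tensor_mode: bool, squeeze: bool):
    if squeeze:
        out = ad.reshape(out, out.data.shape[1:])
    return out if tensor_mode else out.data


def _check_distribution(w: np.ndarray, what: str, tol: float = 1e-5):
    if np.any(w < -tol):
        raise ValueError(f"{what} has negative entries")
    if not np.allclose(w.sum(axis=-1), 1.0, atol=tol):
        raise ValueError(f"{what} does not sum to 1")


# ---------------------------------------------------------------------------
# soft stack
# ---------------------------------------------------------------------------

def stack_update(stack, action, push_value, check: bool = True):
    """One soft stack move; row 0 is the top of the stack.

    ``action`` is a (push, pop, noop) distribution.  The new stack is
    the convex blend  a_push * (shift-down with the pushed value on
    top) + a_pop * (shift-up, zero-padded at the bottom) + a_noop *
    (unchanged); the deepest row is discarded on push.
    """
    tm = _tensor_mode(stack, action, push_value)
    squeeze = _data(stack).ndim == 2
    S = _promote(stack, 3)
    a = _promote(action, 2)
    v = _promote(push_value, 2)
    if check:
        _check_distribution(_data(a), "stack action")
    B, D, W = S.data.shape
    zeros = np.zeros((B, 1, W), dtype=S.data.dtype)
    down = ad.concat([ad.reshape(v, (B, 1, W)),
                      ad.take(S, (slice(None), slice(0, D - 1)))], axis=1)
    up = ad.concat([ad.take(S, (slice(None), slice(1, D))), Tensor(zeros)], axis=1)
    a3 = ad.reshape(a, (B, 3, 1, 1))
    new = (ad.take(a3, (slice(None), 0)) * down
           + ad.take(a3, (slice(None), 1)) * up
           + ad.take(a3, (slice(None), 2)) * S)
    return _finish(new, tm, squeeze)


# ---------------------------------------------------------------------------
# NTM / DNC addressing math
# ---------------------------------------------------------------------------

def content_weights(key, beta, memory, check: bool = True):
    """softmax over locations of beta * cosine_similarity(key, row)."""
    tm = _tensor_mode(key, beta, memory)
    squeeze = _data(key).ndim == 1
    k = _promote(key, 2)            # (B, M)
    M = _promote(memory, 3)         # (B, N, M)
    b = as_tensor(beta)
    if b.data.ndim == 0:
        b = ad.reshape(b, (1, 1))
    elif b.data.ndim == 1:
        b = ad.reshape(b, (b.data.shape[0], 1))
    if check and np.any(_data(b) < 0):
        raise ValueError("key strength beta must be >= 0")
    B, N, Mw = M.data.shape
    dots = ad.reshape(ad.matmul(M, ad.reshape(k, (B, Mw, 1))), (B, N))
    k_norm = ad.sqrt(ad.tsum(k * k, axis=-1, keepdims=True))         # (B,1)
    m_norm = ad.sqrt(ad.tsum(M * M, axis=-1))                        # (B,N)
    sim = dots / (m_norm * k_norm + _EPS_COS)
    w = ad.softmax(b * sim, axis=-1)
    return _finish(w, tm, squeeze)


def ntm_address(prev_w, content_w, g, shift, gamma, check: bool = True):
    """Location addressing: gate, circular shift, sharpen.

    ``shift`` is a distribution over offsets (-K//2 .. +K//2 for odd
    length K, ordered ascending); ``gamma`` must be >= 1.
    """
    if check and np.any(_data(gamma) < 1.0 - 1e-9):
        raise ValueError("sharpening gamma must be >= 1")
    tm = _tensor_mode(prev_w, content_w, g, shift, gamma)
    squeeze = _data(prev_w).ndim == 1
    pw = _promote(prev_w, 2)
    cw = _promote(content_w, 2)
    s = _promote(shift, 2)
    if check:
        _check_distribution(_data(pw), "previous weights")
        _check_distribution(_data(cw), "content weights")
        _check_distribution(_data(s), "shift distribution")
    gt = as_tensor(g)
    if gt.data.ndim == 0:
        gt = ad.reshape(gt, (1, 1))
    elif gt.data.ndim == 1:
        gt = ad.reshape(gt, (gt.data.shape[0], 1))
    gam = as_tensor(gamma)
    if gam.data.ndim == 0:
        gam = ad.reshape(gam, (1, 1))
    elif gam.data.ndim == 1:
        gam = ad.reshape(gam, (gam.data.shape[0], 1))

    wg = gt * cw + (1.0 - gt) * pw
    K = s.data.shape[-1]
    if K % 2 != 1:
        raise ValueError("shift kernel length must be odd")
    half = K // 2
    parts = []
    for j, off in enumerate(range(-half, half + 1)):
        s_j = ad.take(s, (slice(None), slice(j, j + 1)))
        parts.append(s_j * ad.roll(wg, off, axis=-1))
    ws = parts[0]
    for p in parts[1:]:
        ws = ws + p
    # sharpen: w^gamma / sum w^gamma, computed as exp(gamma*log(w))
    wp = ad.exp(gam * ad.log(ws + _EPS_POW))
    w = wp / ad.tsum(wp, axis=-1, keepdims=True)
    return _finish(w, tm, squeeze)


def memory_read(memory, w):
    """Weighted read: w^T M -> an M-vector per batch element."""
    tm = _tensor_mode(memory, w)
    squeeze = _data(w).ndim == 1
    M = _promote(memory, 3)
    wt = _promote(w, 2)
    if M.data.shape[-2] != wt.data.shape[-1]:
        raise ValueError("weight length does not match memory locations")
    B, N, Mw = M.data.shape
    r = ad.reshape(ad.matmul(ad.reshape(wt, (B, 1, N)), M), (B, Mw))
    return _finish(r, tm, squeeze)


def memory_write(memory, w, erase, add, check: bool = True):
    """Erase-then-add write: row_i <- row_i * (1 - w_i e) + w_i a."""
    tm = _tensor_mode(memory, w, erase, add)
    squeeze = _data(w).ndim == 1
    M = _promote(memory, 3)
    wt = _promote(w, 2)
    e = _promote(erase, 2)
    a = _promote(add, 2)
    if check and (np.any(_data(e) < -1e-9) or np.any(_data(e) > 1 + 1e-9)):
        raise ValueError("erase vector must lie in [0,1]")
    if M.data.shape[-2] != wt.data.shape[-1] or M.data.shape[-1] != e.data.shape[-1]:
        raise ValueError("shape mismatch in memory_write")
    B, N, Mw = M.data.shape
    w3 = ad.reshape(wt, (B, N, 1))
    e3 = ad.reshape(e, (B, 1, Mw))
    a3 = ad.reshape(a, (B, 1, Mw))
    new = M * (1.0 - w3 * e3) + w3 * a3
    return _finish(new, tm, squeeze)


def dnc_allocation(usage, check: bool = True):
    """Allocation weighting from usage.

    Locations sorted by ascending usage (ties by index);
    a[phi_j] = (1 - u[phi_j]) * prod_{i<j} u[phi_i].
    """
    ud = _data(usage)
    if check and (np.any(ud < -1e-9) or np.any(ud > 1 + 1e-9)):
        raise ValueError("usage entries must lie in [0,1]")
    tm = _tensor_mode(usage)
    squeeze = ud.ndim == 1
    u = _promote(usage, 2)
    B, N = u.data.shape
    order = np.argsort(u.data, axis=-1, kind="stable")
    rows = np.arange(B)[:, None]
    u_sorted = ad.take(u, (rows, order))
    cp = ad.cumprod(u_sorted, axis=-1)
    ones = Tensor(np.ones((B, 1), dtype=u.data.dtype))
    excl = ad.concat([ones, ad.take(cp, (slice(None), slice(0, N - 1)))], axis=1)
    a_sorted = (1.0 - u_sorted) * excl
    inverse = np.argsort(order, axis=-1)
    a = ad.take(a_sorted, (rows, inverse))
    return _finish(a, tm, squeeze)


def dnc_temporal_update(link, precedence, write_w):
    """Update the temporal link matrix and precedence vector after a write.

    L[i,j] <- (1 - w_i - w_j) L[i,j] + w_i p_j with a forced-zero
    diagonal; p <- (1 - sum w) p + w.
    """
    tm = _tensor_mode(link, precedence, write_w)
    squeeze = _data(write_w).ndim == 1
    L = _promote(link, 3)
    p = _promote(precedence, 2)
    w = _promote(write_w, 2)
    B, N = w.data.shape
    if L.data.shape != (B, N, N):
        raise ValueError("link matrix shape mismatch")
    wi = ad.reshape(w, (B, N, 1))
    wj = ad.reshape(w, (B, 1, N))
    pj = ad.reshape(p, (B, 1, N))
    mask = Tensor((1.0 - np.eye(N, dtype=w.data.dtype))[None, :, :])
    newL = ((1.0 - wi - wj) * L + wi * pj) * mask
    newp = (1.0 - ad.tsum(w, axis=-1, keepdims=True)) * p + w
    if squeeze:
        return (_finish(newL, tm, True), _finish(newp, tm, True))
    return (newL if tm else newL.data, newp if tm else newp.data)


# ---------------------------------------------------------------------------
# controller cores
# ---------------------------------------------------------------------------

def _init_w(rng: np.random.Generator, fan_in: int, shape, dtype):
    return (rng.standard_normal(shape) / np.sqrt(fan_in)).astype(dtype)


class LSTMCore:
    """Fused-gate LSTM used directly as a baseline and as the controller
    of every memory architecture."""

    def __init__(self, store: ParamStore, prefix: str, in_size: int,
                 units: int, rng: np.random.Generator, dtype):
        self.units = units
        self.W = store.add(f"{prefix}.W",
                           _init_w(rng, in_size + units, (in_size + units, 4 * units), dtype))
        b = np.zeros(4 * units, dtype=dtype)
        b[units:2 * units] = 1.0  # forget-gate bias
        self.b = store.add(f"{prefix}.b", b)

    def init_state(self, batch: int, dtype):
        z = np.zeros((batch, self.units), dtype=dtype)
        return Tensor(z), Tensor(z.copy())

    def step(self, x: Tensor, h: Tensor, c: Tensor):
        U = self.units
        z = ad.matmul(ad.concat([x, h], axis=1), self.W) + self.b
        i = ad.sigmoid(ad.take(z, (slice(None), slice(0, U))))
        f = ad.sigmoid(ad.take(z, (slice(None), slice(U, 2 * U))))
        g = ad.tanh(ad.take(z, (slice(None), slice(2 * U, 3 * U))))
        o = ad.sigmoid(ad.take(z, (slice(None), slice(3 * U, 4 * U))))
        c2 = f * c + i * g
        h2 = o * ad.tanh(c2)
        return h2, c2


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

class BaseCell:
    """Interface: ``init_state(batch)`` and ``step(x, state)``;
    ``output_size`` is the width of the feature handed to the logits head."""

    arch: str
    output_size: int

    def init_state(self, batch: int):  # pragma: no cover - interface
        raise NotImplementedError

    def step(self, x: Tensor, state):  # pragma: no cover - interface
        raise NotImplementedError


class RNNCell(BaseCell):
    arch = "rnn"

    def __init__(self, store, in_size, cfg: MemoryConfig, rng, dtype):
        U = cfg.controller_units
        self.units, self.dtype = U, dtype
        self.W = store.add("rnn.W", _init_w(rng, in_size + U, (in_size + U, U), dtype))
        self.b = store.add("rnn.b", np.zeros(U, dtype=dtype))
        self.output_size = U

    def init_state(self, batch):
        return (Tensor(np.zeros((batch, self.units), dtype=self.dtype)),)

    def step(self, x, state):
        (h,) = state
        h2 = ad.tanh(ad.matmul(ad.concat([x, h], axis=1), self.W) + self.b)
        return h2, (h2,)


class GRUCell(BaseCell):
    arch = "gru"

    def __init__(self, store, in_size, cfg: MemoryConfig, rng, dtype):
        U = cfg.controller_units
        self.units, self.dtype = U, dtype
        self.Wzr = store.add("gru.Wzr", _init_w(rng, in_size + U, (in_size + U, 2 * U), dtype))
        self.bzr = store.add("gru.bzr", np.zeros(2 * U, dtype=dtype))
        self.Wh = store.add("gru.Wh", _init_w(rng, in_size + U, (in_size + U, U), dtype))
        self.bh = store.add("gru.bh", np.zeros(U, dtype=dtype))
        self.output_size = U

    def init_state(self, batch):
        return (Tensor(np.zeros((batch, self.units), dtype=self.dtype)),)

    def step(self, x, state):
        (h,) = state
        U = self.units
        zr = ad.sigmoid(ad.matmul(ad.concat([x, h], axis=1), self.Wzr) + self.bzr)
        z = ad.take(zr, (slice(None), slice(0, U)))
        r = ad.take(zr, (slice(None), slice(U, 2 * U)))
        hh = ad.tanh(ad.matmul(ad.concat([x, r * h], axis=1), self.Wh) + self.bh)
        h2 = (1.0 - z) * h + z * hh
        return h2, (h2,)


class LSTMCell(BaseCell):
    arch = "lstm"

    def __init__(self, store, in_size, cfg: MemoryConfig, rng, dtype):
        self.core = LSTMCore(store, "lstm", in_size, cfg.controller_units, rng, dtype)
        self.dtype = dtype
        self.output_size = cfg.controller_units

    def init_state(self, batch):
        return self.core.init_state(batch, self.dtype)

    def step(self, x, state):
        h, c = self.core.step(x, *state)
        return h, (h, c)


class StackRNNCell(BaseCell):
    """LSTM controller + differentiable push-down stack.

    The controller sees the input embedding concatenated with the stack
    top; it emits a (push, pop, noop) action distribution and a pushed
    value squashed by tanh.
    """

    arch = "stackrnn"

    def __init__(self, store, in_size, cfg: MemoryConfig, rng, dtype):
        U, D, W = cfg.controller_units, cfg.n_locations, cfg.word_size
        self.depth, self.width, self.dtype = D, W, dtype
        self.core = LSTMCore(store, "stack.ctrl", in_size + W, U, rng, dtype)
        self.Wa = store.add("stack.Wa", _init_w(rng, U, (U, 3), dtype))
        self.ba = store.add("stack.ba", np.zeros(3, dtype=dtype))
        self.Wv = store.add("stack.Wv", _init_w(rng, U, (U, W), dtype))
        self.bv = store.add("stack.bv", np.zeros(W, dtype=dtype))
        self.output_size = U

    def init_state(self, batch):
        h, c = self.core.init_state(batch, self.dtype)
        stack = Tensor(np.zeros((batch, self.depth, self.width), dtype=self.dtype))
        return h, c, stack

    def step(self, x, state):
        h, c, stack = state
        top = ad.take(stack, (slice(None), 0))
        h2, c2 = self.core.step(ad.concat([x, top], axis=1), h, c)
        action = ad.softmax(ad.matmul(h2, self.Wa) + self.ba, axis=-1)
        value = ad.tanh(ad.matmul(h2, self.Wv) + self.bv)
        stack2 = stack_update(stack, action, value, check=False)
        return h2, (h2, c2, stack2)


class NTMCell(BaseCell):
    """LSTM controller with content+location addressed external memory."""

    arch = "ntm"
    SHIFT_K = 3  # offsets -1, 0, +1

    def __init__(self, store, in_size, cfg: MemoryConfig, rng, dtype):
        U, N, M = cfg.controller_units, cfg.n_locations, cfg.word_size
        R, Wh = cfg.n_read_heads, cfg.n_write_heads
        self.N, self.M, self.R, self.Wn = N, M, R, Wh
        self.dtype = dtype
        self.core = LSTMCore(store, "ntm.ctrl", in_size + R * M, U, rng, dtype)
        # per read head: key M, beta 1, g 1, shift 3, gamma 1
        # per write head: the same + erase M + add M
        self.read_isz = M + 3 + self.SHIFT_K
        self.write_isz = 3 * M + 3 + self.SHIFT_K
        isz = R * self.read_isz + Wh * self.write_isz
        self.Wi = store.add("ntm.Wi", _init_w(rng, U, (U, isz), dtype))
        self.bi = store.add("ntm.bi", np.zeros(isz, dtype=dtype))
        self.output_size = U + R * M

    def init_state(self, batch):
        h, c = self.core.init_state(batch, self.dtype)
        mem = Tensor(np.full((batch, self.N, self.M), 1e-6, dtype=self.dtype))
        w0 = np.zeros((batch, self.N), dtype=self.dtype)
        w0[:, 0] = 1.0
        read_ws = [Tensor(w0.copy()) for _ in range(self.R)]
        write_ws = [Tensor(w0.copy()) for _ in range(self.Wn)]
        reads = [Tensor(np.zeros((batch, self.M), dtype=self.dtype))
                 for _ in range(self.R)]
        return h, c, mem, read_ws, write_ws, reads

    def _head_fields(self, iface, off, with_write: bool):
        M, K = self.M, self.SHIFT_K
        sl = lambda a, b: ad.take(iface, (slice(None), slice(a, b)))
        key = ad.tanh(sl(off, off + M))
        beta = ad.softplus(sl(off + M, off + M + 1))
        g = ad.sigmoid(sl(off + M + 1, off + M + 2))
        shift = ad.softmax(sl(off + M + 2, off + M + 2 + K), axis=-1)
        gamma = ad.oneplus(sl(off + M + 2 + K, off + M + 3 + K))
        out = [key, beta, g, shift, gamma]
        if with_write:
            base = off + M + 3 + K
            out.append(ad.sigmoid(sl(base, base + M)))        # erase
            out.append(ad.tanh(sl(base + M, base + 2 * M)))   # add
        return out

    def _address(self, mem, prev_w, key, beta, g, shift, gamma):
        cw = content_weights(key, beta, mem, check=False)
        return ntm_address(prev_w, cw, g, shift, gamma, check=False)

    def step(self, x, state):
        h, c, mem, read_ws, write_ws, reads = state
        h2, c2 = self.core.step(ad.concat([x] + reads, axis=1), h, c)
        iface = ad.matmul(h2, self.Wi) + self.bi
        off = 0
        # writes first, then reads (reads see the updated memory)
        new_write_ws = []
        woff = self.R * self.read_isz
        for _ in range(self.Wn):
            key, beta, g, shift, gamma, erase, addv = self._head_fields(
                iface, woff, with_write=True)
            w = self._address(mem, write_ws[len(new_write_ws)],
                              key, beta, g, shift, gamma)
            mem = memory_write(mem, w, erase, addv, check=False)
            new_write_ws.append(w)
            woff += self.write_isz
        new_read_ws, new_reads = [], []
        for r in range(self.R):
            key, beta, g, shift, gamma = self._head_fields(
                iface, off, with_write=False)
            w = self._address(mem, read_ws[r], key, beta, g, shift, gamma)
            new_read_ws.append(w)
            new_reads.append(memory_read(mem, w))
            off += self.read_isz
        out = ad.concat([h2] + new_reads, axis=1)
        return out, (h2, c2, mem, new_read_ws, new_write_ws, new_reads)


class DNCCell(BaseCell):
    """LSTM controller with allocation-managed memory and temporal links.

    One write head (standard); ``n_read_heads`` read heads with
    backward/content/forward read modes.
    """

    arch = "dnc"

    def __init__(self, store, in_size, cfg: MemoryConfig, rng, dtype):
        U, N, M, R = (cfg.controller_units, cfg.n_locations,
                      cfg.word_size, cfg.n_read_heads)
        self.N, self.M, self.R = N, M, R
        self.dtype = dtype
        self.core = LSTMCore(store, "dnc.ctrl", in_size + R * M, U, rng, dtype)
        # read head: key M + beta 1 + free gate 1 + 3 read modes
        # write head: key M + beta 1 + erase M + write vector M + alloc gate + write gate
        self.read_isz = M + 5
        self.write_isz = 3 * M + 3
        isz = R * self.read_isz + self.write_isz
        self.Wi = store.add("dnc.Wi", _init_w(rng, U, (U, isz), dtype))
        self.bi = store.add("dnc.bi", np.zeros(isz, dtype=dtype))
        self.output_size = U + R * M

    def init_state(self, batch):
        h, c = self.core.init_state(batch, self.dtype)
        N, M, R = self.N, self.M, self.R
        mem = Tensor(np.full((batch, N, M), 1e-6, dtype=self.dtype))
        w0 = np.zeros((batch, N), dtype=self.dtype)
        w0[:, 0] = 1.0
        read_ws = [Tensor(w0.copy()) for _ in range(R)]
        write_w = Tensor(w0.copy())
        reads = [Tensor(np.zeros((batch, M), dtype=self.dtype)) for _ in range(R)]
        usage = Tensor(np.zeros((batch, N), dtype=self.dtype))
        link = Tensor(np.zeros((batch, N, N), dtype=self.dtype))
        prec = Tensor(np.zeros((batch, N), dtype=self.dtype))
        return h, c, mem, read_ws, write_w, reads, usage, link, prec

    def step(self, x, state):
        h, c, mem, read_ws, write_w, reads, usage, link, prec = state
        N, M, R = self.N, self.M, self.R
        h2, c2 = self.core.step(ad.concat([x] + reads, axis=1), h, c)
        iface = ad.matmul(h2, self.Wi) + self.bi
        sl = lambda a, b: ad.take(iface, (slice(None), slice(a, b)))

        # read-head fields
        r_keys, r_betas, r_frees, r_modes = [], [], [], []
        off = 0
        for _ in range(R):
            r_keys.append(ad.tanh(sl(off, off + M)))
            r_betas.append(ad.softplus(sl(off + M, off + M + 1)))
            r_frees.append(ad.sigmoid(sl(off + M + 1, off + M + 2)))
            r_modes.append(ad.softmax(sl(off + M + 2, off + M + 5), axis=-1))
            off += self.read_isz
        # write-head fields
        w_key = ad.tanh(sl(off, off + M))
        w_beta = ad.softplus(sl(off + M, off + M + 1))
        erase = ad.sigmoid(sl(off + M + 1, off + 2 * M + 1))
        w_vec = ad.tanh(sl(off + 2 * M + 1, off + 3 * M + 1))
        g_alloc = ad.sigmoid(sl(off + 3 * M + 1, off + 3 * M + 2))
        g_write = ad.sigmoid(sl(off + 3 * M + 2, off + 3 * M + 3))

        # usage: retention via free gates, then write-based increase
        psi = None
        for f, wr in zip(r_frees, read_ws):
            term = 1.0 - f * wr
            psi = term if psi is None else psi * term
        usage2 = (usage + write_w - usage * write_w) * psi

        alloc = dnc_allocation(usage2, check=False)
        cw = content_weights(w_key, w_beta, mem, check=False)
        write_w2 = g_write * (g_alloc * alloc + (1.0 - g_alloc) * cw)
        mem2 = memory_write(mem, write_w2, erase, w_vec, check=False)
        link2, prec2 = dnc_temporal_update(link, prec, write_w2)

        new_read_ws, new_reads = [], []
        B = h2.data.shape[0]
        for r in range(R):
            cr = content_weights(r_keys[r], r_betas[r], mem2, check=False)
            fw = ad.reshape(ad.matmul(link2, ad.reshape(read_ws[r], (B, N, 1))), (B, N))
            bw = ad.reshape(ad.matmul(ad.transpose(link2, (0, 2, 1)),
                                      ad.reshape(read_ws[r], (B, N, 1))), (B, N))
            m = r_modes[r]
            w = (ad.take(m, (slice(None), slice(0, 1))) * bw
                 + ad.take(m, (slice(None), slice(1, 2))) * cr
                 + ad.take(m, (slice(None), slice(2, 3))) * fw)
            new_read_ws.append(w)
            new_reads.append(memory_read(mem2, w))
        out = ad.concat([h2] + new_reads, axis=1)
        return out, (h2, c2, mem2, new_read_ws, write_w2, new_reads,
                     usage2, link2, prec2)


_CELLS = {"rnn": RNNCell, "gru": GRUCell, "lstm": LSTMCell,
          "stackrnn": StackRNNCell, "ntm": NTMCell, "dnc": DNCCell}


def make_cell(arch: str, store: ParamStore, in_size: int,
              cfg: MemoryConfig, rng: np.random.Generator,
              dtype=np.float32) -> BaseCell:
    if arch not in _CELLS:
        raise ValueError(f"unknown architecture {arch!r}; "
                         f"expected one of {ARCHITECTURES}")
    return _CELLS[arch](store, in_size, cfg, rng, dtype)


class SequenceModel:
    """Embedding -> recurrent cell -> linear logits head.

    The shared backbone of the SMILES generators and the copy-task
    models; ``n_outputs`` is the softmax width (vocabulary size) or the
    number of output units for non-token tasks.
    """

    def __init__(self, arch: str, n_inputs: int, n_outputs: int,
                 cfg: MemoryConfig, seed: int = 0, dtype=np.float32,
                 embed_tokens: bool = True):
        self.arch = arch
        self.cfg = cfg
        self.n_inputs = n_inputs
        self.n_outputs = n_outputs
        self.dtype = dtype
        self.embed_tokens = embed_tokens
        self.store = ParamStore()
        rng = np.random.default_rng(seed)
        E = cfg.embedding_length
        if embed_tokens:
            self.embed = self.store.add(
                "embed", (rng.standard_normal((n_inputs, E)) * 0.1).astype(dtype))
            in_size = E
        else:
            self.embed = None
            in_size = n_inputs
        self.cell = make_cell(arch, self.store, in_size, cfg, rng, dtype)
        self.Wo = self.store.add(
            "out.W", _init_w(rng, self.cell.output_size,
                             (self.cell.output_size, n_outputs), dtype))
        self.bo = self.store.add("out.b", np.zeros(n_outputs, dtype=dtype))

    def init_state(self, batch: int):
        return self.cell.init_state(batch)

    def step_features(self, x, state):
        """One recurrent step without the logits head (training loops
        stack features over time and apply the head once)."""
        if self.embed_tokens:
            x = ad.take(self.embed, np.asarray(x, dtype=np.intp))
        else:
            x = as_tensor(x)
        return self.cell.step(x, state)

    def head(self, features):
        """Logits from cell features; accepts (B, H) or stacked (T*B, H)."""
        return ad.matmul(features, self.Wo) + self.bo

    def step(self, x, state):
        """One step.  ``x``: int token array (B,) if embedding, else a
        (B, n_inputs) array/tensor.  Returns (logits (B, n_outputs), state)."""
        feat, state = self.step_features(x, state)
        return self.head(feat), state


def cell_step(model: SequenceModel, state, x):
    """Functional one-step interface: returns (logits, new_state)."""
    return model.step(x, state)
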