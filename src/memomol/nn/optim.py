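"""Optimizers and parameter-collection utilities for the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


class ParamStore:
    """A flat, named collection of trainable tensors.

    Models in this package register every weight here; the store is the
    single unit of serialization (``state_dict`` round-trips through an
    ``.npz`` archive written by the model checkpoints).
    """

    def __init__(self):
        self._params: dict[str, Tensor] = {}

    def add(self, name: str, array: np.ndarray) -> Tensor:
        if name in self._params:
            raise ValueError(f"duplicate parameter name: {name}")
        t = Tensor(np.asarray(array), requires_grad=True)
        self._params[name] = t
        return t

    def __getitem__(self, name: str) -> Tensor:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def items(self):
        return self._params.items()

    def tensors(self):
        return list(self._params.values())

    def zero_grad(self):
        for t in self._params.values():
            t.grad = None

    def n_weights(self) -> int:
        return sum(t.data.size for t in self._params.values())

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self._params.items()}

    def load_state_dict(self, state: dict):
        missing = set(self._params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in checkpoint: {sorted(missing)}")
        for k, t in self._params.items():
            arr = np.asarray(state[k])
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"shape mismatch for {k}: {arr.shape} vs {t.data.shape}")
            t.data = arr.astype(t.data.dtype)


def clip_global_norm(params, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for t in params:
        if t.grad is not None:
            total += float((t.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for t in params:
            if t.grad is not None:
                t.grad = t.grad * scale
    return norm


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data = p.data - self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
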