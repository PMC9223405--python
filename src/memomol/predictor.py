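"""Character-level CNN regression from a SMILES string to a property.

The network embeds each token (inventory: chemical tokens + one unknown
slot, 46 in the default vocabulary, plus a padding row), applies five
convolution + max-pooling stages, flattens, and finishes with
ReLU dense layers, dropout and a linear scalar head.  Training
minimizes mean squared error with Adam on an 80-20 train/test split;
inference is deterministic (dropout disabled) and accepts any string,
valid or not, since the input is just characters.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from .nn import autodiff as ad
from .nn.optim import Adam, ParamStore, clip_global_norm
from .tokenizer import TokenVocabulary


@dataclass
class PredictorConfig:
    input_length: int = 121          # 98% of full-scale strings fit
    embedding_width: int = 46
    n_conv_layers: int = 5
    conv_channels: tuple = (32, 64, 128, 128, 128)
    kernel_size: int = 3
    pool_size: int = 2
    dense_units: tuple = (128,)
    dropout: float = 0.5
    learning_rate: float = 1e-3
    batch_size: int = 64
    epochs: int = 20
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.input_length < 1:
            raise ValueError("input_length must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0,1)")
        if self.n_conv_layers != len(self.conv_channels):
            raise ValueError("n_conv_layers must equal len(conv_channels)")


def encode_for_predictor(smiles: str, vocab: TokenVocabulary,
                         input_length: int,
                         overflow: str = "truncate") -> np.ndarray:
    """Fixed-length index sequence in the predictor's compact space.

    Chemical tokens keep their vocabulary indices, anything unknown maps
    to the unknown slot, and the sequence is right-padded with the
    dedicated padding row (index ``vocab.chem_size``).  Longer strings
    are truncated (default) or rejected (``overflow='error'``).
    """
    idx = vocab.encode(smiles)
    if len(idx) > input_length:
        if overflow == "error":
            raise ValueError(f"string longer than input_length={input_length}")
        idx = idx[:input_length]
    out = np.full(input_length, vocab.chem_size, dtype=np.intp)
    out[:len(idx)] = idx
    return out


class PropertyPredictor:
    """The char-CNN regressor; one scalar property per model."""

    def __init__(self, vocab: TokenVocabulary,
                 config: Optional[PredictorConfig] = None,
                 dtype=np.float32):
        self.vocab = vocab
        self.config = config or PredictorConfig()
        self.dtype = dtype
        cfg = self.config
        self.store = ParamStore()
        rng = np.random.default_rng(cfg.seed)
        n_rows = vocab.chem_size + 1  # + padding row
        self.embed = self.store.add(
            "embed", (rng.standard_normal((n_rows, cfg.embedding_width)) * 0.1
                      ).astype(dtype))
        # conv stack; track the sequence length through conv+pool
        L = cfg.input_length
        cin = cfg.embedding_width
        self._conv = []
        for li, cout in enumerate(cfg.conv_channels):
            L = L - cfg.kernel_size + 1
            if L < 1:
                raise ValueError("input_length too short for the conv stack")
            W = self.store.add(f"conv{li}.W",
                               _he(rng, cfg.kernel_size * cin,
                                   (cfg.kernel_size * cin, cout), dtype))
            b = self.store.add(f"conv{li}.b", np.zeros(cout, dtype=dtype))
            self._conv.append((W, b))
            cin = cout
            if L >= cfg.pool_size:
                L = L // cfg.pool_size
        flat = L * cin
        self._dense = []
        for di, units in enumerate(cfg.dense_units):
            W = self.store.add(f"dense{di}.W", _he(rng, flat, (flat, units), dtype))
            b = self.store.add(f"dense{di}.b", np.zeros(units, dtype=dtype))
            self._dense.append((W, b))
            flat = units
        self.Wo = self.store.add("out.W", _he(rng, flat, (flat, 1), dtype))
        self.bo = self.store.add("out.b", np.zeros(1, dtype=dtype))

    # -- forward ------------------------------------------------------
    def forward(self, idx: np.ndarray, train_rng=None):
        """(B, input_length) indices -> (B,) prediction tensor."""
        cfg = self.config
        x = ad.take(self.embed, np.asarray(idx, dtype=np.intp))
        for W, b in self._conv:
            win = ad.unfold1d(x, cfg.kernel_size)
            x = ad.relu(ad.matmul(win, W) + b)
            if x.data.shape[1] >= cfg.pool_size:
                x = ad.maxpool1d(x, cfg.pool_size)
        B = x.data.shape[0]
        x = ad.reshape(x, (B, -1))
        for W, b in self._dense:
            x = ad.relu(ad.matmul(x, W) + b)
        x = ad.dropout(x, cfg.dropout, train_rng)
        out = ad.matmul(x, self.Wo) + self.bo
        return ad.reshape(out, (B,))

    def encode_batch(self, smiles: Sequence[str]) -> np.ndarray:
        return np.stack([encode_for_predictor(s, self.vocab,
                                              self.config.input_length)
                         for s in smiles])

    def predict(self, smiles) -> np.ndarray:
        """Deterministic inference; accepts a string or a sequence."""
        single = isinstance(smiles, str)
        batch = [smiles] if single else list(smiles)
        with ad.no_grad():
            out = self.forward(self.encode_batch(batch)).data.astype(float)
        return float(out[0]) if single else out

    def as_scorer(self):
        """A str -> float callable for the RL biasing loop."""
        return lambda s: float(self.predict(s))

    # -- training -----------------------------------------------------
    def fit(self, smiles: Sequence[str], targets: Sequence[float],
            log: Optional[list] = None) -> float:
        """Train on an 80-20 split; returns held-out MSE.

        Strings longer than ``input_length`` are dropped from training
        (kept-out fraction is appended to ``log`` if given).
        """
        cfg = self.config
        pairs = [(s, float(y)) for s, y in zip(smiles, targets)]
        if len(pairs) < 10:
            raise ValueError("need at least 10 training pairs")
        if not all(np.isfinite(y) for _, y in pairs):
            raise ValueError("targets must be finite")
        keep = [(s, y) for s, y in pairs
                if len(self.vocab.encode(s)) <= cfg.input_length]
        n_dropped = len(pairs) - len(keep)
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(keep))
        n_test = max(1, int(round(0.2 * len(keep))))
        test_idx, train_idx = order[:n_test], order[n_test:]
        X = self.encode_batch([keep[i][0] for i in range(len(keep))])
        y = np.array([keep[i][1] for i in range(len(keep))], dtype=self.dtype)
        opt = Adam(self.store.tensors(), lr=cfg.learning_rate)
        drop_rng = np.random.default_rng(cfg.seed + 1)
        for epoch in range(cfg.epochs):
            perm = rng.permutation(train_idx)
            losses = []
            for s0 in range(0, len(perm), cfg.batch_size):
                sel = perm[s0:s0 + cfg.batch_size]
                pred = self.forward(X[sel], train_rng=drop_rng)
                err = pred - y[sel]
                loss = ad.tmean(err * err)
                v = loss.item()
                if not np.isfinite(v):
                    raise FloatingPointError(
                        f"non-finite loss in epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                clip_global_norm(self.store.tensors(), cfg.clip_norm)
                opt.step()
                losses.append(v)
            if log is not None:
                log.append({"epoch": epoch, "train_mse": float(np.mean(losses)),
                            "n_dropped": n_dropped})
        with ad.no_grad():
            preds = []
            for s0 in range(0, len(test_idx), 256):
                sel = test_idx[s0:s0 + 256]
                preds.append(self.forward(X[sel]).data)
        test_pred = np.concatenate(preds)
        return float(np.mean((test_pred - y[test_idx]) ** 2))

    # -- persistence ----------------------------------------------------
    def save(self, path):
        meta = {"config": asdict(self.config), "vocab": self.vocab.to_json(),
                "dtype": np.dtype(self.dtype).name, "format": 1}
        meta["config"]["conv_channels"] = list(self.config.conv_channels)
        meta["config"]["dense_units"] = list(self.config.dense_units)
        buf = io.BytesIO()
        np.savez(buf, **self.store.state_dict())
        with zipfile.ZipFile(path, "w") as z:
            z.writestr("meta.json", json.dumps(meta))
            z.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "PropertyPredictor":
        with zipfile.ZipFile(path) as z:
            meta = json.loads(z.read("meta.json"))
            weights = np.load(io.BytesIO(z.read("weights.npz")))
            state = {k: weights[k] for k in weights.files}
        c = meta["config"]
        c["conv_channels"] = tuple(c["conv_channels"])
        c["dense_units"] = tuple(c["dense_units"])
        model = cls(TokenVocabulary.from_json(meta["vocab"]),
                    PredictorConfig(**c), dtype=np.dtype(meta["dtype"]).type)
        model.store.load_state_dict(state)
        return model


def _he(rng, fan_in, shape, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def train_predictor(pairs, config: Optional[PredictorConfig] = None,
                    vocab: Optional[TokenVocabulary] = None):
    """Train from (smiles, value) pairs; returns (model, test MSE)."""
    from .tokenizer import build_vocabulary
    smiles = [p[0] for p in pairs]
    targets = [p[1] for p in pairs]
    if vocab is None:
        vocab = build_vocabulary(smiles)
    model = PropertyPredictor(vocab, config)
    mse = model.fit(smiles, targets)
    return model, mse
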