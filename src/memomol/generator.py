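"""Teacher-forced training of SMILES generators and stochastic generation.

Training minimizes per-token categorical cross-entropy of the next
token given the ground-truth prefix (sparse softmax cross-entropy),
sampling batches with replacement so progress is counted in iterations,
not epochs.  At a configurable interval the trainer generates a sample
batch and records its validity percentage, giving the
iteration-vs-valid% checkpoint table used to monitor convergence.

Generation builds each string token by token from the start token until
the end token or a length cap.  The next token comes from a two-branch
stochastic rule: with probability 1 - epsilon a single draw from the
model's softmax; otherwise ``n_samples`` draws are deduplicated and one
of the distinct candidates is chosen uniformly — boosting the odds of
low-probability tokens to encourage exploration.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np

from . import chem
from .cells import MemoryConfig, SequenceModel
from .nn import autodiff as ad
from .nn.optim import Adam, clip_global_norm
from .tokenizer import TokenVocabulary


@dataclass
class GenerationPolicy:
    """Stochastic sampling rule for string generation.

    epsilon: probability of the exploration branch; n_samples: draws in
    that branch (distinct values are chosen among uniformly);
    max_length: token cap per string (120 matches the training cap of
    the full-scale corpus).
    """

    epsilon: float = 0.05
    n_samples: int = 5
    max_length: int = 120

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0,1]")
        if self.n_samples < 1 or self.max_length < 1:
            raise ValueError("n_samples and max_length must be >= 1")


@dataclass
class TrainConfig:
    iterations: int = 20000
    batch_size: int = 26           # full-scale default (StackRNN/DNC)
    eval_every: int = 5000
    eval_sample: int = 200         # strings generated per checkpoint
    learning_rate: float = 1e-3
    clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        for name in ("iterations", "batch_size", "eval_every", "eval_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def get_next_character(dist: np.ndarray, policy: GenerationPolicy,
                       rng: np.random.Generator) -> int:
    """Draw one token index from a distribution under the two-branch rule."""
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 1 or np.any(dist < -1e-9) or abs(dist.sum() - 1.0) > 1e-5:
        raise ValueError("dist must be a 1-D probability distribution")
    cdf = np.cumsum(dist)
    cdf[-1] = 1.0
    if rng.random() > policy.epsilon:
        return int(np.searchsorted(cdf, rng.random(), side="right"))
    draws = np.searchsorted(cdf, rng.random(policy.n_samples), side="right")
    uniq = np.unique(draws)
    return int(uniq[rng.integers(len(uniq))])


class GeneratedBatch(list):
    """List of generated SMILES strings; ``n_truncated`` counts strings
    cut at max_length without emitting the end token."""

    def __init__(self, strings=(), n_truncated: int = 0):
        super().__init__(strings)
        self.n_truncated = n_truncated


class SmilesGenerator:
    """A vocabulary-aware sequence model over SMILES tokens."""

    def __init__(self, arch: str, vocab: TokenVocabulary,
                 mem: Optional[MemoryConfig] = None, seed: int = 0,
                 dtype=np.float32):
        self.arch = arch
        self.vocab = vocab
        self.mem = mem if mem is not None else MemoryConfig()
        self.model = SequenceModel(arch, vocab.size, vocab.size, self.mem,
                                   seed=seed, dtype=dtype)
        self._init_seed = seed

    # -- data ---------------------------------------------------------
    def encode_corpus(self, corpus: Sequence[str]) -> list[np.ndarray]:
        """start + tokens + end, as index arrays."""
        if len(corpus) == 0:
            raise ValueError("empty corpus")
        v = self.vocab
        out = []
        for s in corpus:
            out.append(np.array([v.start_index] + v.encode(s) + [v.end_index],
                                dtype=np.intp))
        return out

    def _pad_batch(self, seqs: list[np.ndarray]) -> np.ndarray:
        T = max(len(s) for s in seqs)
        out = np.full((len(seqs), T), self.vocab.pad_index, dtype=np.intp)
        for i, s in enumerate(seqs):
            out[i, :len(s)] = s
        return out

    # -- training -----------------------------------------------------
    def loss_on_batch(self, padded: np.ndarray):
        """Masked next-token cross-entropy (natural log) on a padded batch."""
        B, T = padded.shape
        inputs, targets = padded[:, :-1], padded[:, 1:]
        # pads may appear as inputs after the end token; they are masked
        # out of the loss so their predictions are irrelevant
        state = self.model.init_state(B)
        feats = []
        for t in range(T - 1):
            f, state = self.model.step_features(inputs[:, t], state)
            feats.append(f)
        logits = self.model.head(ad.concat(feats, axis=0))      # (T-1)*B rows
        logp = ad.log_softmax(logits, axis=-1)
        flat_targets = targets.T.reshape(-1)                     # t-major
        mask = (flat_targets != self.vocab.pad_index).astype(logits.data.dtype)
        picked = ad.take(logp, (np.arange(flat_targets.size), flat_targets))
        return -ad.tsum(picked * mask) / float(mask.sum())

    def train(self, corpus: Sequence[str], config: TrainConfig,
              policy: Optional[GenerationPolicy] = None,
              log_every: int = 100) -> list[dict]:
        """Train in place; returns the log (loss every ``log_every``
        iterations, validity %% of a generated sample every
        ``config.eval_every``)."""
        encoded = self.encode_corpus(corpus)
        rng = np.random.default_rng(config.seed)
        eval_rng_seed = np.random.SeedSequence(config.seed).spawn(1)[0]
        policy = policy or GenerationPolicy()
        opt = Adam(self.model.store.tensors(), lr=config.learning_rate)
        log: list[dict] = []
        for it in range(1, config.iterations + 1):
            idx = rng.integers(0, len(encoded), size=config.batch_size)
            batch = self._pad_batch([encoded[i] for i in idx])
            loss = self.loss_on_batch(batch)
            val = loss.item()
            if not np.isfinite(val):
                raise FloatingPointError(
                    f"non-finite loss at iteration {it}: {val}")
            opt.zero_grad()
            loss.backward()
            clip_global_norm(self.model.store.tensors(), config.clip_norm)
            opt.step()
            entry = None
            if it % log_every == 0 or it == config.iterations:
                entry = {"iteration": it, "loss": val}
            if it % config.eval_every == 0:
                sample = self.generate(
                    config.eval_sample, policy,
                    rng=np.random.default_rng([eval_rng_seed.entropy, it]))
                valid = 100.0 * np.mean([chem.check_validity(s) for s in sample])
                entry = entry or {"iteration": it, "loss": val}
                entry["valid_pct"] = float(valid)
                entry["n_truncated"] = sample.n_truncated
            if entry:
                log.append(entry)
        return log

    # -- generation -----------------------------------------------------
    def generate(self, count: int, policy: Optional[GenerationPolicy] = None,
                 rng: Optional[np.random.Generator] = None,
                 seed: Optional[int] = None) -> GeneratedBatch:
        """Generate ``count`` SMILES strings (specials stripped)."""
        policy = policy or GenerationPolicy()
        if rng is None:
            rng = np.random.default_rng(seed)
        v = self.vocab
        out: list[str] = []
        n_trunc = 0
        B = min(count, 64)
        with ad.no_grad():
            while len(out) < count:
                b = min(B, count - len(out))
                tokens, truncated = self._sample_batch(b, policy, rng)
                n_trunc += truncated
                out.extend(v.decode(t) for t in tokens)
        return GeneratedBatch(out, n_trunc)

    def _sample_batch(self, b: int, policy: GenerationPolicy,
                      rng: np.random.Generator, collect_graph: bool = False):
        """Shared sampling loop.  Returns (token lists, n_truncated) and,
        with ``collect_graph``, also per-step logits tensors and choices
        for RL training."""
        v = self.vocab
        state = self.model.init_state(b)
        current = np.full(b, v.start_index, dtype=np.intp)
        alive = np.ones(b, dtype=bool)
        tokens: list[list[int]] = [[] for _ in range(b)]
        steps_logits, steps_choice, steps_alive = [], [], []
        for _ in range(policy.max_length):
            feats, state = self.model.step_features(current, state)
            logits = self.model.head(feats)
            probs = _softmax_np(logits.data)
            nxt = np.array([get_next_character(probs[i], policy, rng)
                            if alive[i] else v.pad_index
                            for i in range(b)], dtype=np.intp)
            if collect_graph:
                steps_logits.append(logits)
                steps_choice.append(nxt.copy())
                steps_alive.append(alive.copy())
            for i in range(b):
                if alive[i] and nxt[i] != v.end_index:
                    tokens[i].append(int(nxt[i]))
            alive &= nxt != v.end_index
            if not alive.any():
                break
            current = np.where(alive, nxt, v.pad_index)
        n_trunc = int(alive.sum())
        if collect_graph:
            return tokens, n_trunc, steps_logits, steps_choice, steps_alive
        return tokens, n_trunc

    def rollout(self, b: int, policy: GenerationPolicy,
                rng: np.random.Generator):
        """Sample a batch while retaining the graph.

        Returns (strings, per-string sequence cross-entropy (b,) tensor)
        where the cross-entropy is the summed negative log-likelihood of
        each string's own sampled tokens (end token included).
        """
        tokens, n_trunc, logits_t, choice_t, alive_t = self._sample_batch(
            b, policy, rng, collect_graph=True)
        T = len(logits_t)
        logp = ad.log_softmax(ad.concat(logits_t, axis=0), axis=-1)  # (T*b, V)
        flat_choice = np.concatenate(choice_t)
        mask = np.concatenate(alive_t).astype(logp.data.dtype)
        picked = ad.take(logp, (np.arange(T * b), flat_choice)) * mask
        per_string = ad.tsum(ad.reshape(picked, (T, b)), axis=0)
        strings = GeneratedBatch((self.vocab.decode(t) for t in tokens), n_trunc)
        return strings, -per_string

    def clone(self) -> "SmilesGenerator":
        """An independent copy with identical weights."""
        g = SmilesGenerator(self.arch, self.vocab, self.mem,
                            seed=self._init_seed, dtype=self.model.dtype)
        g.model.store.load_state_dict(self.model.store.state_dict())
        return g

    # -- persistence ----------------------------------------------------
    def save(self, path):
        """Single-archive checkpoint: weights (npz) + JSON config/vocab."""
        meta = {
            "arch": self.arch,
            "mem": asdict(self.mem),
            "vocab": self.vocab.to_json(),
            "dtype": np.dtype(self.model.dtype).name,
            "format": 1,
        }
        buf = io.BytesIO()
        np.savez(buf, **self.model.store.state_dict())
        with zipfile.ZipFile(path, "w") as z:
            z.writestr("meta.json", json.dumps(meta))
            z.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "SmilesGenerator":
        with zipfile.ZipFile(path) as z:
            meta = json.loads(z.read("meta.json"))
            weights = np.load(io.BytesIO(z.read("weights.npz")))
            state = {k: weights[k] for k in weights.files}
        vocab = TokenVocabulary.from_json(meta["vocab"])
        gen = cls(meta["arch"], vocab, MemoryConfig(**meta["mem"]),
                  dtype=np.dtype(meta["dtype"]).type)
        gen.model.store.load_state_dict(state)
        return gen


def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def train_generator(corpus: Sequence[str], arch: str, config: TrainConfig,
                    mem: Optional[MemoryConfig] = None,
                    vocab: Optional[TokenVocabulary] = None):
    """Build a vocabulary (from the corpus unless given), train a
    generator, and return (generator, log)."""
    from .tokenizer import build_vocabulary
    if vocab is None:
        vocab = build_vocabulary(corpus)
    gen = SmilesGenerator(arch, vocab, mem, seed=config.seed)
    log = gen.train(corpus, config)
    return gen, log
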