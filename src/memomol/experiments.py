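"""Desk-scale experiment harnesses.

These wrap the library into the reproducible experiments the package
ships: the copy-task probe of external memory, SMILES generator
training on the fixture corpus with the iteration-vs-validity
checkpoint table, the capacity comparison between a memory-augmented
generator and an LSTM at matched controller size, and property-biasing
runs with before/after statistics.

Problem sizes here are deliberately small (16-32 controller units, a
few thousand iterations, a 5,000-molecule synthetic corpus) so each
experiment finishes in minutes on one CPU while preserving the
qualitative behaviour of the full-scale setup.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from . import chem
from .cells import MemoryConfig, SequenceModel
from .fixtures import copy_batch, smiles_corpus, toy_property_oracle
from .generator import (GenerationPolicy, SmilesGenerator, TrainConfig,
                        train_generator)
from .nn import autodiff as ad
from .nn.optim import Adam, clip_global_norm
from .rl import RewardConfig, bias_generator

# ---------------------------------------------------------------------------
# copy task
# ---------------------------------------------------------------------------

COPY_BITS = 6

#: per-architecture learning rates with stable convergence at 16 units
COPY_LR = {"ntm": 3e-3, "dnc": 5e-3, "lstm": 3e-3, "gru": 3e-3,
           "rnn": 3e-3, "stackrnn": 3e-3}


def _copy_forward(model: SequenceModel, x: np.ndarray, y: np.ndarray):
    """Run the model over a copy sequence; loss on the recall steps only."""
    T, B, _ = x.shape
    L = y.shape[0]
    state = model.init_state(B)
    feats = []
    for t in range(T):
        f, state = model.step_features(x[t], state)
        if t >= T - L:
            feats.append(f)
    z = model.head(ad.concat(feats, axis=0))
    yt = y.reshape(L * B, -1)
    loss = ad.tmean(ad.softplus(z) - z * yt)   # binary cross-entropy
    return loss, z


def copy_bit_accuracy(model: SequenceModel, length: int, seed: int = 9,
                      n_batches: int = 5, batch: int = 32,
                      bits: int = COPY_BITS) -> float:
    """Held-out fraction of correctly recalled bits at one length."""
    rng = np.random.default_rng(seed)
    accs = []
    with ad.no_grad():
        for _ in range(n_batches):
            x, y = copy_batch(rng, batch, length, bits)
            _, z = _copy_forward(model, x, y)
            accs.append(((z.data > 0) == (y.reshape(-1, bits) > 0.5)).mean())
    return float(np.mean(accs))


def train_copy_model(arch: str, seed: int, controller_units: int = 16,
                     n_locations: int = 24, word_size: int = 10,
                     bits: int = COPY_BITS, min_len: int = 1,
                     max_len: int = 8, batch: int = 32,
                     max_iters: int = 3000, min_iters: int = 1000,
                     target_acc: float = 0.998, eval_every: int = 100,
                     lr: Optional[float] = None):
    """Train one model on the copy task with early stopping.

    Returns (model, info) where info records iterations used and the
    evaluation trace.
    """
    cfg = MemoryConfig(n_locations=n_locations, word_size=word_size,
                       controller_units=controller_units,
                       embedding_length=bits + 2)
    model = SequenceModel(arch, bits + 2, bits, cfg, seed=seed,
                          embed_tokens=False)
    opt = Adam(model.store.tensors(), lr=lr if lr is not None else COPY_LR[arch])
    rng = np.random.default_rng(seed + 1000)
    trace = []
    stopped = max_iters
    for it in range(1, max_iters + 1):
        L = int(rng.integers(min_len, max_len + 1))
        x, y = copy_batch(rng, batch, L, bits)
        loss, _ = _copy_forward(model, x, y)
        opt.zero_grad()
        loss.backward()
        clip_global_norm(model.store.tensors(), 10.0)
        opt.step()
        if it % eval_every == 0:
            acc = copy_bit_accuracy(model, max_len, n_batches=3)
            trace.append({"iteration": it, "loss": loss.item(), "acc": acc})
            if acc >= target_acc and it >= min_iters:
                stopped = it
                break
    return model, {"arch": arch, "seed": seed, "iterations": stopped,
                   "trace": trace}


def copy_task_experiment(archs: Sequence[str] = ("ntm", "dnc", "lstm"),
                         seeds: Sequence[int] = (1, 2, 3),
                         gen_length: int = 16, **train_kw) -> dict:
    """Per-architecture copy accuracy at the training lengths and at a
    longer generalization length, averaged over seeds."""
    out: dict = {}
    for arch in archs:
        acc_train, acc_gen = [], []
        for seed in seeds:
            model, info = train_copy_model(arch, seed, **train_kw)
            acc_train.append(copy_bit_accuracy(model, train_kw.get("max_len", 8)))
            acc_gen.append(copy_bit_accuracy(model, gen_length))
        out[arch] = {
            "acc_train_lengths": acc_train,
            "acc_generalization": acc_gen,
            "mean_acc_train": float(np.mean(acc_train)),
            "mean_acc_generalization": float(np.mean(acc_gen)),
        }
    return out


# ---------------------------------------------------------------------------
# fixture-corpus generator training
# ---------------------------------------------------------------------------

def fixture_memory_config(units: int = 32, stack_width: int = 16,
                          memory_rows: int = 50,
                          embedding: int = 32) -> MemoryConfig:
    """Desk-scale memory shape (full-scale defaults live in MemoryConfig)."""
    return MemoryConfig(n_locations=memory_rows, word_size=stack_width,
                        controller_units=units, embedding_length=embedding)


def train_fixture_generator(arch: str, units: int = 32,
                            iterations: int = 20000, seed: int = 1,
                            corpus: Optional[Sequence[str]] = None,
                            corpus_n: int = 5000, corpus_seed: int = 0,
                            batch_size: int = 26, eval_every: int = 2000,
                            eval_sample: int = 200,
                            learning_rate: float = 3e-3,
                            stack_width: int = 16, memory_rows: int = 50):
    """Train a generator on the procedural corpus; returns
    (generator, log, corpus)."""
    if corpus is None:
        corpus = smiles_corpus(corpus_n, seed=corpus_seed)
    mem = fixture_memory_config(units, stack_width, memory_rows)
    cfg = TrainConfig(iterations=iterations, batch_size=batch_size,
                      eval_every=eval_every, eval_sample=eval_sample,
                      learning_rate=learning_rate, seed=seed)
    gen, log = train_generator(corpus, arch, cfg, mem)
    return gen, log, corpus


def validity_curve(log: Sequence[dict]) -> list[tuple[int, float]]:
    """(iteration, valid %) checkpoints from a training log."""
    return [(e["iteration"], e["valid_pct"]) for e in log if "valid_pct" in e]


def trend_slope(curve: Sequence[tuple[int, float]]) -> float:
    """Least-squares slope of valid % against iteration."""
    if len(curve) < 2:
        raise ValueError("need at least two checkpoints")
    x = np.array([c[0] for c in curve], dtype=float)
    y = np.array([c[1] for c in curve], dtype=float)
    return float(np.polyfit(x, y, 1)[0])


def capacity_comparison(archs: Sequence[str] = ("stackrnn", "lstm"),
                        units: int = 16, seeds: Sequence[int] = (1, 2, 3),
                        iterations: int = 1500,
                        corpus: Optional[Sequence[str]] = None,
                        sample: int = 200, **train_kw) -> dict:
    """Final validity % per architecture and seed at matched controller
    size.  The comparison is reported, not asserted: single seeds can
    order either way."""
    if corpus is None:
        corpus = smiles_corpus(5000, seed=0)
    results: dict = {a: [] for a in archs}
    for arch in archs:
        for seed in seeds:
            gen, log, _ = train_fixture_generator(
                arch, units=units, iterations=iterations, seed=seed,
                corpus=corpus, eval_every=iterations, eval_sample=sample,
                **train_kw)
            curve = validity_curve(log)
            results[arch].append(curve[-1][1])
    summary = {a: {"valid_pct_per_seed": v, "mean_valid_pct": float(np.mean(v))}
               for a, v in results.items()}
    summary["units"] = units
    summary["iterations"] = iterations
    summary["seeds"] = list(seeds)
    return summary


# ---------------------------------------------------------------------------
# biasing experiments
# ---------------------------------------------------------------------------

DEFAULT_BIAS_POLICY = GenerationPolicy(epsilon=0.05, n_samples=5,
                                       max_length=60)


def bias_experiment(base: SmilesGenerator,
                    scorer: Callable[[str], float] = toy_property_oracle,
                    direction: str = "minimize",
                    loss_mode: str = "reinforce",
                    n_steps: int = 200, magnitude: float = 0.25,
                    batch_size: int = 24, learning_rate: float = 3e-4,
                    seed: int = 3, n_eval: int = 500,
                    policy: GenerationPolicy = DEFAULT_BIAS_POLICY,
                    reference: Optional[Sequence[str]] = None) -> dict:
    """Bias a copy of ``base`` and compare property distributions.

    Invalid strings are scored with a direction-appropriate penalty
    (the worst property value) so the biased model keeps generating
    parseable molecules.  Returns medians, the one-sided Mann-Whitney
    p-value for a shift in the commanded direction, and validity before
    and after.
    """
    penalty = 30.0 if direction == "minimize" else 0.0
    cfg = RewardConfig.for_direction(
        direction, magnitude, loss_mode=loss_mode, batch_size=batch_size,
        learning_rate=learning_rate, seed=seed,
        invalid_policy="penalty", penalty_value=penalty)
    biased = base.clone()
    history = bias_generator(biased, scorer, cfg, n_steps, policy)

    eval_seed = seed + 77
    base_sample = base.generate(n_eval, policy, seed=eval_seed)
    biased_sample = biased.generate(n_eval, policy, seed=eval_seed + 1)
    p_base = np.array([scorer(s) for s in base_sample])
    p_biased = np.array([scorer(s) for s in biased_sample])
    alternative = "less" if direction == "minimize" else "greater"
    stat, pvalue = mannwhitneyu(p_biased, p_base, alternative=alternative)
    out = {
        "direction": direction,
        "loss_mode": loss_mode,
        "n_steps_run": len(history),
        "median_unbiased": float(np.median(p_base)),
        "median_biased": float(np.median(p_biased)),
        "mean_unbiased": float(np.mean(p_base)),
        "mean_biased": float(np.mean(p_biased)),
        "mannwhitney_p": float(pvalue),
        "valid_pct_unbiased": 100.0 * float(np.mean(
            [chem.check_validity(s) for s in base_sample])),
        "valid_pct_biased": 100.0 * float(np.mean(
            [chem.check_validity(s) for s in biased_sample])),
    }
    if reference is not None:
        from .metrics import percent_common
        vb = [s for s in base_sample if chem.check_validity(s)]
        vz = [s for s in biased_sample if chem.check_validity(s)]
        if vb and vz:
            out["common_pct_unbiased"] = percent_common(vb, reference)
            out["common_pct_biased"] = percent_common(vz, reference)
    out["biased_generator"] = biased
    return out
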