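"""Policy-gradient property biasing of a trained generator.

The loop: sample a batch of strings from the current generator, score
each with a property predictor (or any scalar oracle), form the
exponential property loss ``exp(p*s)``, combine it with the sequence
cross-entropy of the sampled tokens, and take one optimizer step.  The
sign convention couples the scaling factor to the commanded direction:
minimizing a property uses s > 0 (high p ⇒ high loss), maximizing uses
s < 0.

Two loss modes are provided because the printed additive objective and
the policy-gradient view differ in how the property term reaches the
generator weights:

* ``reinforce`` (default) — the score-function estimator: each string's
  cross-entropy is weighted by its batch-centered exponential loss
  (advantage), so strings whose ``exp(p*s)`` is below the batch mean
  have their likelihood increased and vice versa.  The property term
  influences the gradient; this is the standard REINFORCE form.
* ``literal`` — the additive objective ``mean(exp(p*s)) + mean(CE)``
  exactly as written; since p is computed on discrete sampled strings,
  the property term carries no generator gradient, so the CE term is
  restricted to the best-scoring fraction of the batch (cross-entropy
  -method-style selection) to make the mode directional.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from . import chem
from .generator import GenerationPolicy, SmilesGenerator
from .nn import autodiff as ad
from .nn.optim import Adam, clip_global_norm

DIRECTIONS = ("minimize", "maximize")
LOSS_MODES = ("reinforce", "literal")
INVALID_POLICIES = ("score_anyway", "skip", "penalty")


@dataclass
class RewardConfig:
    """Configuration of the biasing loop.

    ``s`` scales the property inside ``exp(p*s)``; its sign must match
    the direction (minimize -> s > 0, maximize -> s < 0).
    ``invalid_policy`` decides how unparsable strings are scored:
    scored like any string (the char-level predictor accepts them),
    dropped from the loss, or given a fixed penalty property value.
    """

    direction: str = "minimize"
    s: float = 0.5
    batch_size: int = 32
    learning_rate: float = 5e-4
    loss_mode: str = "reinforce"
    invalid_policy: str = "score_anyway"
    penalty_value: float = 0.0
    selection_fraction: float = 0.5   # literal mode: CE over best fraction
    clip_exponent: float = 30.0       # bound on p*s before exponentiation
    validity_floor: float = 0.05      # divergence guard (fraction valid)
    clip_norm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.loss_mode not in LOSS_MODES:
            raise ValueError(f"loss_mode must be one of {LOSS_MODES}")
        if self.invalid_policy not in INVALID_POLICIES:
            raise ValueError(f"invalid_policy must be one of {INVALID_POLICIES}")
        if not np.isfinite(self.s) or self.s == 0.0:
            raise ValueError("scaling factor s must be finite and nonzero")
        if self.direction == "minimize" and self.s < 0:
            raise ValueError("direction=minimize requires s > 0")
        if self.direction == "maximize" and self.s > 0:
            raise ValueError("direction=maximize requires s < 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must lie in (0,1]")

    @classmethod
    def for_direction(cls, direction: str, magnitude: float = 0.5, **kw):
        """Build a config with the sign convention applied for you."""
        s = abs(magnitude) if direction == "minimize" else -abs(magnitude)
        return cls(direction=direction, s=s, **kw)


def predicted_loss(p, s: float, clip_exponent: float = 30.0):
    """exp(p*s), elementwise, with the exponent clipped to +-clip_exponent."""
    z = np.asarray(p, dtype=float) * float(s)
    clipped = np.clip(z, -clip_exponent, clip_exponent)
    return np.exp(clipped)


def _score_batch(strings: Sequence[str], scorer: Callable[[str], float],
                 cfg: RewardConfig):
    """Property values and the loss-inclusion mask per invalid_policy."""
    valid = np.array([chem.check_validity(s) for s in strings])
    p = np.empty(len(strings), dtype=float)
    include = np.ones(len(strings), dtype=bool)
    for i, s in enumerate(strings):
        if valid[i] or cfg.invalid_policy == "score_anyway":
            p[i] = scorer(s)
        elif cfg.invalid_policy == "penalty":
            p[i] = cfg.penalty_value
        else:  # skip
            p[i] = np.nan
            include[i] = False
    return p, include, valid


def bias_step(generator: SmilesGenerator, scorer: Callable[[str], float],
              cfg: RewardConfig, policy: GenerationPolicy,
              opt: Adam, rng: np.random.Generator) -> dict:
    """One generate-score-update step; returns batch diagnostics."""
    strings, ce = generator.rollout(cfg.batch_size, policy, rng)
    if len(strings) == 0:
        raise ValueError("empty generation batch")
    p, include, valid = _score_batch(strings, scorer, cfg)
    if not include.any():
        raise ValueError("no strings left to score (all invalid with "
                         "invalid_policy='skip')")
    pl = predicted_loss(np.where(include, p, 0.0), cfg.s, cfg.clip_exponent)
    w_inc = include.astype(ce.data.dtype)
    n_inc = float(w_inc.sum())

    if cfg.loss_mode == "reinforce":
        # reward = -exp(p*s); coefficient (R_i - mean R) on each string's
        # CE, so below-average-loss strings become more likely
        mean_pl = float((pl * w_inc).sum() / n_inc)
        adv = (mean_pl - pl) * w_inc
        std = float(np.std(adv[include]))
        if std > 1e-12:
            adv = adv / std
        loss = ad.tsum(ce * adv.astype(ce.data.dtype)) / n_inc
        reported = float(loss.item() + mean_pl)
    else:  # literal: mean exp term (no gradient) + CE over the best slice
        order = np.argsort(np.where(include, pl, np.inf), kind="stable")
        k = max(1, int(round(cfg.selection_fraction * n_inc)))
        sel = np.zeros(len(strings), dtype=ce.data.dtype)
        sel[order[:k]] = 1.0
        mean_pl = float((pl * w_inc).sum() / n_inc)
        loss = ad.tsum(ce * sel) / float(k)
        reported = float(loss.item() + mean_pl)

    opt.zero_grad()
    loss.backward()
    clip_global_norm(generator.model.store.tensors(), cfg.clip_norm)
    opt.step()
    return {
        "mean_p": float(np.nanmean(np.where(include, p, np.nan))),
        "median_p": float(np.nanmedian(np.where(include, p, np.nan))),
        "mean_loss": reported,
        "valid_pct": 100.0 * float(valid.mean()),
        "mean_length": float(np.mean([len(s) for s in strings])),
        "n_truncated": strings.n_truncated,
    }


def bias_generator(generator: SmilesGenerator, scorer: Callable[[str], float],
                   cfg: RewardConfig, n_steps: int,
                   policy: Optional[GenerationPolicy] = None) -> list[dict]:
    """Iterate :func:`bias_step` n_steps times (in place); returns history.

    Stops early (recording ``stopped_early``) if batch validity falls
    below ``cfg.validity_floor``.
    """
    policy = policy or GenerationPolicy()
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(generator.model.store.tensors(), lr=cfg.learning_rate)
    history: list[dict] = []
    for step in range(1, n_steps + 1):
        diag = bias_step(generator, scorer, cfg, policy, opt, rng)
        diag["step"] = step
        history.append(diag)
        if diag["valid_pct"] < 100.0 * cfg.validity_floor:
            diag["stopped_early"] = True
            break
    return history
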