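# Methods

This note records the models implemented in `memomol`, the choices
made where the design was genuinely open, the synthetic data the
package trains on, and what the tests do and do not establish.

## Generators

All six architectures share one interface: an embedding layer, a
recurrent cell, and a linear logits head over the token vocabulary
(`memomol.cells.SequenceModel`). The controller of every
memory-augmented cell is a single-layer LSTM with a fused gate matrix
and forget-gate bias 1.

**StackRNN.** The controller input is the token embedding concatenated
with the stack top. From the hidden state the cell emits a
(push, pop, no-op) softmax action and a tanh-squashed push value. The
stack update is the convex blend

    S' = a_push * (shift-down with v on top) + a_pop * (shift-up) + a_noop * S

with zeros entering at the bottom on pop and the deepest row discarded
on push. With one-hot actions this is exactly a bounded classical
stack (tested against a list-based oracle).

**NTM.** Memory is an N x M matrix. Each head addresses it by content
— softmax over β · cosine(key, row), with an additive 1e-8 guard in
the norm product — followed by location addressing: gated
interpolation with the previous weighting (gate g), circular
convolution with a 3-tap shift distribution over offsets {-1, 0, +1},
and sharpening w^γ / Σ w^γ computed as exp(γ·log(w + 1e-16)). Writes
are erase-then-add; reads are wᵀM. Interface squashings: β via
softplus, g and erase via sigmoid, shift via softmax, γ via
1 + softplus, keys and add vectors via tanh. Write heads act before
read heads within a step, so reads see the updated memory.

**DNC.** One write head and R read heads (default 1). Usage is
retained through free gates, u ← (u + w_w − u∘w_w) ∘ Π(1 − f·w_r);
allocation sorts locations by ascending usage (ties by index) and sets
a[φ_j] = (1 − u[φ_j]) Π_{i<j} u[φ_i]; the write weighting gates
allocation against content lookup, w_w = g_w (g_a·a + (1−g_a)·c). The
temporal link update is L ← (1 − w_i − w_j)∘L + w_i p_j with a forced
zero diagonal, and precedence p ← (1 − Σw) p + w. Read weightings mix
backward (Lᵀ w_r), content and forward (L w_r) modes through a 3-way
softmax. A consequence worth stating: DNC read and write weightings
are *sub-stochastic* (entries ≥ 0, sum ≤ 1), not distributions — at
initialization the link matrix is zero, so the temporal read modes
contribute no mass. Tests assert sum-to-one for NTM heads and the
sub-simplex plus link-matrix invariants for the DNC.

State initialization is deterministic: memory constant 1e-6, head
weightings one-hot at location 0, usage/precedence/link zero, hidden
states zero.

**Full-scale vs desk-scale shapes.** `MemoryConfig` defaults to the
full-scale geometry: 200 memory rows / stack depth (chosen so strings
up to 120 tokens cannot overflow), and 1024-wide rows, embeddings and
controllers. Experiments in this package run a desk-scale geometry
(`experiments.fixture_memory_config`): 16–32 controller units, 50
stack rows of width 16, 32-wide embeddings — small enough to converge
in minutes on one CPU while preserving the architecture.

## Generator training and generation

Training is teacher-forced next-token prediction with per-token
categorical cross-entropy on integer targets, masked at padding.
Batches are drawn with replacement from the corpus, so progress is
counted in iterations rather than epochs. Adam (1e-3 default; the
desk-scale experiments use 3e-3) with global-norm gradient clipping
at 5. Every `eval_every` iterations the trainer generates a sample
batch and records its validity %, producing the checkpoint table used
to compare architectures.

Generation builds each string from the start token until the end token
or `max_length` (default 120, the training cap; desk-scale experiments
use 60 since fixture molecules are short). The next token follows the
two-branch rule: draw u ~ U(0,1); if u > ε take one multinomial draw
from the softmax; otherwise draw `n_samples` times, deduplicate, and
choose uniformly among the distinct candidates. Defaults ε = 0.05,
n_samples = 5. The exploration branch provably lifts the probability
of low-probability tokens; the test suite checks the implementation
against an exact enumeration of the two-stage process on two-token
distributions.

The vocabulary is derived from the training corpus by a longest-match
scan over a declared table (bracket atoms and %nn closures as single
tokens, two-letter elements Cl/Br) and serialized inside every
checkpoint, so generation, prediction and evaluation always agree on
the token inventory. A default 45-token inventory (+ unknown slot) is
provided for corpus-free use.

## Property predictor

A character-level CNN: token indices (chemical tokens + unknown, a
dedicated padding row) → embedding of width 46 → five stages of
valid-mode convolution (kernel 3; channels 32, 64, 128, 128, 128) each
followed by max-pooling of width 2 → flatten → dense 128 with ReLU →
dropout 0.5 → linear scalar. Input length 121 tokens; longer strings
are dropped in training and truncated (with the event counted) at
inference. Targets are raw-scale (unstandardized). Training is Adam
on MSE with an 80-20 split; the held-out MSE is the reported score.
The conv/dense widths are conventional choices, exposed in
`PredictorConfig`; nothing in the package depends on them beyond the
tests' accuracy floors.

The full-scale reference for this component is an MSE of order 0.08
for logP when trained on ~200k real drug-like molecules; that is not
reproduced here (external data, long training). The desk-scale
surrogates are: R² > 0.9 on a synthetic token-count property over the
5,000-molecule fixture corpus, and R² ≈ 0.98–0.99 for logP on the same
corpus, both recomputed by the acceptance script. The degenerate
constant-target check runs with dropout disabled, because with dropout
on the residual measures regularization noise rather than the
optimizer.

## Reinforcement-learning biasing

Each step samples a batch from the current generator (same ε/n rule,
so exploration persists), scores every string with a predictor or
oracle, and forms the exponential property loss exp(p·s) with the
exponent clipped to ±30. The sign convention ties s to the commanded
direction: minimize → s > 0, maximize → s < 0, enforced at config
validation.

Two loss modes:

* **reinforce** (default). The score-function estimator with a batch
  baseline: reward R_i = −exp(p_i·s), coefficient (R_i − mean R)
  normalized by its batch standard deviation, loss
  mean(coef_i · (−log π(string_i))). Strings whose exponential loss is
  below the batch mean get their likelihood increased, the rest
  decreased. Note the direction of the weighting: multiplying the
  *cross-entropy* by the raw exponential loss would reinforce the
  worst strings; the reward-centered form is the standard estimator
  and is what makes the declared s-sign convention bias the right way.
* **literal**. The additive objective mean(exp(p·s)) + mean(CE) taken
  at face value. Because p is computed on discrete sampled strings,
  the property term has zero generator gradient; biasing then comes
  from batch-level selection: the CE term is computed over the
  best-scoring half of the batch (fraction configurable), a
  cross-entropy-method-style hill climber. The exponential term is
  still reported in the diagnostics.

Invalid strings are handled by a configurable policy: scored like any
string (the char-CNN accepts arbitrary text; default), dropped, or
assigned a fixed penalty property value. The biasing *experiments*
use the penalty policy with a direction-appropriate worst value
(30 heavy atoms for minimize, 0 for maximize), which anchors validity
during maximization — without it the generator discovers that long
invalid strings also raise the oracle score. A divergence guard stops
the loop if batch validity falls below a configurable floor (default
5%).

Experiment defaults (|s| = 0.25, learning rate 3e-4, batch 24, 200
steps, generation cap 60 tokens) were chosen so that both modes and
both directions shift the generated property median decisively on the
fixture corpus while validity stays within a few points of the
unbiased model; they are defaults of the harness, not of the library.

Novelty (100 − common %) is computed and reported before and after
biasing but not asserted: the fixture corpus densely covers its tiny
molecule space, so minimize-direction biasing (toward very small
molecules) *raises* overlap with the training set — the opposite
regime from a sparse multi-hundred-thousand-molecule corpus, where
biased models drift into unseen chemistry.

## Synthetic data

`memomol.fixtures` provides three seeded, pure generators:

* **smiles** — molecules grown as random trees of C/N/O atoms with
  explicit valence bookkeeping, optional branches, and up to
  `ring_sites` phenyl substituents each attached with probability
  `ring_prob`; output is canonicalized, so every string is valid by
  construction. Defaults: 5,000 molecules, ≤ 20 heavy atoms, mean
  string length ≈ 9 characters, benzene count distributed
  ~Binomial(2, 0.35), heavy-atom variance ≈ 10. This gives every
  stage signal (validity learnable, properties non-degenerate) at a
  scale where 16–32-unit models converge in minutes.
* **copy** — the external-memory probe: 6-bit patterns of length 1–8
  between start/delimiter flags, to be reproduced after the delimiter.
* **dyck** — balanced bracket strings over configurable pairs with a
  depth cap, plus a counter-based membership oracle.

What the fixture corpus does *not* emulate: real pharmacological
property distributions, stereochemistry, charged/bracket atoms, fused
or non-aromatic rings, and string lengths beyond ~25 characters.
Passing tests therefore demonstrate that the machinery works — cells
are correct and differentiable, training converges, biasing moves
distributions in the commanded direction — not that the desk-scale
models would match full-scale results on real chemistry.

## Problem sizes used by tests and the acceptance script

Chosen so the full suite runs in well under half an hour on one CPU:

* Copy task: 16-unit controllers, 24 memory rows of width 10, batch
  32, up to 3,000 iterations with early stopping (≥ 99.8% accuracy on
  the training lengths after ≥ 1,000 iterations); NTM learning rate
  3e-3, DNC 5e-3 (the DNC converges more reliably slightly hotter);
  generalization probed at length 16; three seeds.
* Language-model check: 32-unit StackRNN, 10,000 iterations at batch
  32 on the 5,000-molecule corpus, validity checkpoints every 1,000
  iterations (200 samples each). The capacity comparison
  (StackRNN vs LSTM at 16 units, 3 seeds) runs 1,500 iterations and is
  reported, not asserted — single seeds can order either way.
* Predictor: 5,000 molecules, 15 epochs for the R² check.
* Biasing: LSTM base generator (24 units, 1,500 iterations), 200 bias
  steps per direction/mode, 500 evaluation strings per side,
  one-sided Mann–Whitney at α = 0.01.
* The acceptance script condenses the same study (3,000-iteration
  generator, 12-epoch predictors, single-seed copy runs) into ~5
  minutes.

## Numerical choices and degenerate inputs

Cosine similarity guards the norm product with 1e-8 (all-zero keys or
rows give uniform content weights); sharpening guards the logarithm
with 1e-16; exponential rewards clip the exponent at ±30; gradients
are clipped by global norm (5 for language-model training, 10 for the
copy task, 1 for biasing). Allocation sorting breaks ties by location
index (stable argsort). The cumulative product used by allocation has
a zero-safe O(N) backward recurrence (no division by usage values).
Quartiles use linear (type-7) interpolation; average string length is
counted in raw characters (a token-count mode exists). Common %
canonicalizes both sides before the set intersection; a flag restores
literal comparison. Models default to float32; gradient checks build
float64 cells.

## Known limitations

* Single-layer controllers only; at most a few heads; no batched
  multi-layer DNC.
* The NumPy engine executes one op at a time, so wall-clock cost is
  dominated by per-op overhead: fine for 16–64-unit models, not meant
  for the 1024-unit full-scale geometry.
* The literal loss mode is a selection heuristic around an objective
  whose property term is flat in the generator weights; conclusions
  about "the" additive objective should rest on the reinforce mode.
* Checkpoints serialize weights and config but not optimizer state;
  resuming training restarts the optimizer.
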