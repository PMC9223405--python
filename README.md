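# memomol

Memory-augmented recurrent generators for de-novo small-molecule
design, with a character-level CNN property predictor and a
policy-gradient loop that biases generation toward a property target.

## The problem

De-novo design frameworks built on SMILES language models face a
structural challenge: a valid SMILES string requires every opened ring
digit and bracket to be closed, possibly far downstream, and a plain
recurrent network has only its hidden state to remember those
obligations. This package implements three recurrent generators whose
memory is *external* to the hidden state —

* **StackRNN** — an LSTM controller coupled to a differentiable
  push-down stack driven by soft (push, pop, no-op) actions;
* **NTM** (Neural Turing Machine) — an LSTM controller with an N x M
  memory matrix addressed by content (cosine similarity, key strength
  β) and location (gated interpolation g, circular shift s, sharpening
  γ), with erase/add writes;
* **DNC** (Differentiable Neural Computer) — the NTM plus usage-based
  allocation a(u), a precedence vector and a temporal link matrix L
  supporting forward/backward reads —

alongside RNN / GRU / LSTM baselines, all exposed as drop-in sequence
cells. A generator is pretrained by teacher forcing (sparse softmax
cross-entropy on the next token) and evaluated by the fraction of
generated strings that parse into molecules (validity %) and the
fraction overlapping the training set (common %; novelty is its
complement).

A character-level CNN (token embedding over a 46-slot inventory, five
convolution + max-pooling stages, ReLU dense head with dropout 0.5,
Adam, MSE loss) predicts a property p (e.g. logP) from the raw string.
A reinforcement-learning loop then biases the generator: strings are
sampled with a two-branch stochastic rule (with probability 1−ε a
single softmax draw; otherwise n draws deduplicated and one distinct
candidate chosen uniformly, boosting exploration), each string is
scored, the exponential loss **exp(p·s)** is formed (minimize → s>0,
maximize → s<0), and a REINFORCE-style update weights each string's
sequence cross-entropy by its batch-centered exponential loss. Both
this estimator and the literal additive objective are implemented (see
`docs/methods.md`).

Everything is trainable and testable at desk scale with no downloads:
a bundled procedural generator emits guaranteed-valid SMILES corpora
(plus copy-task and Dyck-language fixtures for probing the memory
cells), and RDKit computes validity, logP, benzene-ring counts,
molecular weight and the Ertl–Schuffenhauer synthetic-accessibility
(SA) score.

All networks run on a small reverse-mode autodiff engine over NumPy
arrays (`memomol.nn`), so the package needs no deep-learning framework;
finite-difference gradient checks on the NTM and DNC cells are part of
the test suite.

## Worked example

Train a 32-unit StackRNN on a 2,000-molecule synthetic corpus and
sample from it (`python examples/02_train_generator.py`, about a
minute):

```
iteration   valid %
      500     85.0
     1000     88.0
     1500     97.0
     2000     96.0

sampled molecules: ['Oc1ccccc1', 'CCOC', 'Oc1ccccc1', 'NCCCc1ccccc1', ...]
```

Validity climbing from 85% to ~96% across checkpoints means the model
learned SMILES syntax — matched ring digits, balanced parentheses,
valence-consistent atoms — from raw strings alone.

Bias a pretrained generator to *minimize* molecular size
(`python examples/05_bias_generator.py`):

```
heavy-atom median:  unbiased 7.0  ->  biased 3.0
validity:           unbiased 97.0%  ->  biased 97.8%
one-sided Mann-Whitney p: 7.97e-78
```

The property median halves while validity is unchanged: the policy
gradient reshapes *which* molecules are produced without destroying
the learned syntax. The other scripts in `examples/` cover the
corpus generator, the copy-task probe of external memory (a 16-unit
NTM reaches ~100% bit recall where the same-size LSTM manages ~68%),
the logP predictor (held-out R² ≈ 0.98 at desk scale), and the full
config-driven pipeline.

A thin CLI mirrors the pipeline stages:

```bash
memomol make-fixtures --kind smiles --n 5000 --seed 0 --out corpus.smi
memomol train-generator --arch stackrnn --corpus corpus.smi --units 32 \
        --iterations 2000 --eval-every 500 --seed 1 --out gen.ckpt
memomol generate --model gen.ckpt --count 500 --seed 2 --out lib.smi
memomol evaluate --generated lib.smi --reference corpus.smi \
        --property logP --out report.json
memomol bias --model gen.ckpt --direction minimize --steps 200 --out biased.ckpt
memomol run config.yaml          # all stages from one file
```

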