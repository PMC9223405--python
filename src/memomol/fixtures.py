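"""Synthetic corpora for training and testing every stage at desk scale.

Three generators, all pure functions of a :class:`FixtureSpec` (seed
included), so identical specs give byte-identical output:

* **copy** — the classic external-memory probe: a flagged sequence of
  random bit vectors must be reproduced after a delimiter.
* **dyck** — balanced-bracket strings, the classical probe of stack-like
  capability.
* **smiles** — procedurally grown molecules, guaranteed valid by
  explicit valence bookkeeping, with tunable benzene-ring and branching
  probabilities so property-biasing experiments have signal.

The SMILES generator is a stand-in for a real training corpus (e.g. a
ChEMBL subset): it emulates a distribution of drug-like strings at a
scale where 16-32-unit generators converge on one CPU in minutes.  It
does not emulate real pharmacological property distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .tokenizer import scan_tokens, TWO_CHAR_TOKENS

_VALENCE = {"C": 4, "N": 3, "O": 2}

#: tokens that contribute one heavy atom each (for the toy oracle)
_ATOM_TOKENS = {"C", "N", "O", "S", "P", "F", "I", "B", "Cl", "Br",
                "c", "n", "o", "s", "p"}

DEFAULT_SMILES_PARAMS = dict(
    atom_weights={"C": 0.7, "N": 0.2, "O": 0.1},
    ring_sites=2,          # candidate phenyl attachment points
    ring_prob=0.35,        # phenyl attachment probability per site
    branch_prob=0.35,
    min_backbone=3,
    max_backbone=8,
    max_heavy_atoms=20,
)

DEFAULT_COPY_PARAMS = dict(bits=6, min_length=1, max_length=8)
DEFAULT_DYCK_PARAMS = dict(pairs=("()", "[]"), max_depth=4,
                           min_length=0, max_length=40)


@dataclass
class FixtureSpec:
    """What to generate: ``kind`` in {copy, dyck, smiles}, count, seed,
    and kind-specific ``params`` (unset keys take the defaults above)."""

    kind: str
    n: int
    seed: int = 0
    params: dict = field(default_factory=dict)

    def merged_params(self) -> dict:
        base = {"copy": DEFAULT_COPY_PARAMS, "dyck": DEFAULT_DYCK_PARAMS,
                "smiles": DEFAULT_SMILES_PARAMS}[self.kind]
        out = dict(base)
        unknown = set(self.params) - set(base)
        if unknown:
            raise ValueError(f"unknown params for kind={self.kind}: {sorted(unknown)}")
        out.update(self.params)
        return out


# ---------------------------------------------------------------------------
# copy task
# ---------------------------------------------------------------------------

def copy_batch(rng: np.random.Generator, batch: int, length: int, bits: int):
    """One batch of copy sequences of a single length.

    Input layout per timestep: ``bits`` pattern channels + start flag +
    delimiter flag; the pattern must be emitted during the ``length``
    steps after the delimiter.  Returns (x (T,B,bits+2), y (L,B,bits)).
    """
    pats = (rng.random((length, batch, bits)) < 0.5).astype(np.float32)
    T = 2 * length + 2
    x = np.zeros((T, batch, bits + 2), dtype=np.float32)
    x[0, :, bits] = 1.0
    x[1:length + 1, :, :bits] = pats
    x[length + 1, :, bits + 1] = 1.0
    return x, pats


def gen_copy_task(spec: FixtureSpec):
    """n (input, target) pairs with lengths uniform in the configured range."""
    if spec.kind != "copy":
        raise ValueError("spec.kind must be 'copy'")
    p = spec.merged_params()
    if not (1 <= p["min_length"] <= p["max_length"]):
        raise ValueError("invalid copy length range")
    rng = np.random.default_rng(spec.seed)
    xs, ys = [], []
    for _ in range(spec.n):
        L = int(rng.integers(p["min_length"], p["max_length"] + 1))
        x, y = copy_batch(rng, 1, L, p["bits"])
        xs.append(x[:, 0])
        ys.append(y[:, 0])
    return xs, ys


# ---------------------------------------------------------------------------
# Dyck language
# ---------------------------------------------------------------------------

def _dyck_one(rng, pairs, max_depth, max_len) -> str:
    out = []
    depth_stack = []
    while len(out) < max_len:
        if not depth_stack and rng.random() < 0.15:
            break  # allow short (incl. empty) strings
        can_open = (len(depth_stack) < max_depth
                    and len(out) + len(depth_stack) + 2 <= max_len)
        if depth_stack and (not can_open or rng.random() < 0.5):
            out.append(depth_stack.pop())
        elif can_open:
            pair = pairs[int(rng.integers(len(pairs)))]
            out.append(pair[0])
            depth_stack.append(pair[1])
        else:
            break
    # close whatever is still open, innermost first
    out.extend(reversed(depth_stack))
    return "".join(out)


def gen_dyck(spec: FixtureSpec) -> list[str]:
    """Balanced bracket strings over the configured pairs."""
    if spec.kind != "dyck":
        raise ValueError("spec.kind must be 'dyck'")
    p = spec.merged_params()
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n):
        s = ""
        for _ in range(50):  # resample until min_length satisfied
            s = _dyck_one(rng, p["pairs"], p["max_depth"], p["max_length"])
            if len(s) >= p["min_length"]:
                break
        out.append(s)
    return out


def is_balanced(s: str, pairs=("()", "[]")) -> bool:
    """Counter/stack oracle for Dyck membership."""
    close_of = {p[0]: p[1] for p in pairs}
    closers = {p[1] for p in pairs}
    stack = []
    for ch in s:
        if ch in close_of:
            stack.append(close_of[ch])
        elif ch in closers:
            if not stack or stack.pop() != ch:
                return False
        else:
            return False
    return not stack


# ---------------------------------------------------------------------------
# procedural SMILES
# ---------------------------------------------------------------------------

def _grow_chain(rng, n_atoms, atoms, weights, branch_prob, ring_slots,
                ring_prob) -> str:
    """Random tree of single-bonded C/N/O atoms written directly as
    SMILES; ``ring_slots`` is a mutable count of remaining phenyl sites."""
    atom = rng.choice(atoms, p=weights)
    free = _VALENCE[atom] - 1  # one bond to the parent
    parts = [atom]
    budget = n_atoms - 1
    children = []
    while budget > 0 and free > 0:
        if ring_slots[0] > 0 and rng.random() < ring_prob:
            # phenyl substituent; rings never nest, so digit 1 is free
            ring_slots[0] -= 1
            children.append("c1ccccc1")
            free -= 1
            continue
        if children and rng.random() >= branch_prob:
            break
        take = int(rng.integers(1, budget + 1))
        children.append(_grow_chain(rng, take, atoms, weights, branch_prob,
                                    ring_slots, ring_prob))
        budget -= take
        free -= 1
    for i, c in enumerate(children):
        if i < len(children) - 1:
            parts.append(f"({c})")
        else:
            parts.append(c)
    return "".join(parts)


def gen_procedural_smiles(spec: FixtureSpec) -> list[str]:
    """Guaranteed-valid molecules as canonical SMILES.

    Molecules are random trees of C/N/O atoms with explicit valence
    bookkeeping plus up to ``ring_sites`` phenyl substituents, each
    attached with probability ``ring_prob``; strings are canonicalized
    by the chemistry backend before being returned.
    """
    if spec.kind != "smiles":
        raise ValueError("spec.kind must be 'smiles'")
    p = spec.merged_params()
    rng = np.random.default_rng(spec.seed)
    atoms = sorted(p["atom_weights"])
    weights = np.array([p["atom_weights"][a] for a in atoms], dtype=float)
    weights = weights / weights.sum()
    out = []
    for _ in range(spec.n):
        n_rings = int((rng.random(p["ring_sites"]) < p["ring_prob"]).sum())
        max_backbone = min(p["max_backbone"],
                           max(p["min_backbone"], p["max_heavy_atoms"] - 6 * n_rings))
        n_atoms = int(rng.integers(p["min_backbone"], max_backbone + 1))
        ring_slots = [n_rings]
        raw = _grow_chain(rng, n_atoms, atoms, weights,
                          p["branch_prob"], ring_slots, 0.9)
        if ring_slots[0] > 0:
            # unplaced phenyls bond to the backbone head, whose parent
            # valence slot is reserved by construction
            raw = "c1ccccc1" * ring_slots[0] + raw
        can = chem.canonicalize(raw)
        if can is None:  # pragma: no cover - construction guarantees validity
            raise AssertionError(f"procedural SMILES invalid: {raw!r}")
        out.append(can)
    return out


def smiles_corpus(n: int = 5000, seed: int = 0, **params) -> list[str]:
    """The default fixture corpus (5,000 molecules of <= 20 heavy atoms)."""
    return gen_procedural_smiles(FixtureSpec(kind="smiles", n=n, seed=seed,
                                             params=params))


def generate(spec: FixtureSpec):
    """Dispatch on ``spec.kind``."""
    if spec.kind == "copy":
        return gen_copy_task(spec)
    if spec.kind == "dyck":
        return gen_dyck(spec)
    if spec.kind == "smiles":
        return gen_procedural_smiles(spec)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# toy property oracle
# ---------------------------------------------------------------------------

def toy_property_oracle(smiles: str, mode: str = "heavy_atoms") -> float:
    """A cheap deterministic property usable as an RL reward source.

    ``heavy_atoms`` counts atom tokens in the string (defined for any
    string, valid or not); ``benzene_rings`` delegates to the chemistry
    backend for valid strings and returns 0 for invalid ones.
    """
    if mode == "heavy_atoms":
        count = 0
        for tok in scan_tokens(smiles, TWO_CHAR_TOKENS):
            if tok in _ATOM_TOKENS or tok.startswith("["):
                count += 1
        return float(count)
    if mode == "benzene_rings":
        if not chem.check_validity(smiles):
            return 0.0
        return chem.compute_property(smiles, "benzene_rings")
    raise ValueError(f"unknown oracle mode {mode!r}")
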