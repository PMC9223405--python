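"""SMILES tokenization and the token vocabulary shared by all models.

SMILES strings mix single-character tokens (atoms of the organic subset,
ring-closure digits, bonds, branch parentheses) with multi-character
ones: two-letter halogens ``Cl``/``Br``, bracket atoms such as
``[C@@H]`` or ``[O-]`` (treated as one token each), and ``%nn``
ring closures.  Tokenization is a deterministic longest-match scan over
a declared table, so the token <-> index mapping is a bijection and
``detokenize(tokenize(s)) == s`` whenever every token of ``s`` is known.

The vocabulary holds the chemical tokens plus one *unknown* slot (the
inventory a property predictor embeds — 46 slots in the default
configuration) and three generator-only specials: start, end and pad.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

UNK = "<unk>"
START = "^"
END = "$"
PAD = "<pad>"

#: Two-letter element tokens recognised outside brackets.
TWO_CHAR_TOKENS = ("Cl", "Br")

#: A 45-token SMILES inventory covering drug-like organic chemistry;
#: together with the unknown slot this gives the default 46-slot
#: embedding table of the property predictor.
DEFAULT_SMILES_TOKENS: tuple[str, ...] = (
    "C", "N", "O", "S", "P", "F", "I", "B", "Cl", "Br",
    "c", "n", "o", "s",
    "1", "2", "3", "4", "5", "6", "7", "8",
    "(", ")",
    "-", "=", "#", "/", "\\", ".",
    "[nH]", "[n+]", "[N+]", "[N-]", "[O-]", "[S-]", "[S+]",
    "[C@H]", "[C@@H]", "[C@]", "[C@@]", "[Se]", "[Si]", "[P+]", "[B-]",
)

assert len(DEFAULT_SMILES_TOKENS) == 45


class VocabularyError(ValueError):
    """Raised when a vocabulary cannot be built (e.g. empty corpus)."""


def scan_tokens(smiles: str, two_char: Sequence[str] = TWO_CHAR_TOKENS) -> list[str]:
    """Longest-match scan of a SMILES string into tokens.

    Bracket atoms ``[...]`` and ``%nn`` ring closures are single tokens;
    two-letter elements are matched before their one-letter prefixes.
    An unterminated ``[`` falls back to a single-character token.
    """
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.find("]", i + 1)
            if j != -1:
                tokens.append(smiles[i:j + 1])
                i = j + 1
                continue
        elif ch == "%" and i + 2 < n + 1 and smiles[i + 1:i + 3].isdigit():
            tokens.append(smiles[i:i + 3])
            i += 3
            continue
        elif smiles[i:i + 2] in two_char:
            tokens.append(smiles[i:i + 2])
            i += 2
            continue
        tokens.append(ch)
        i += 1
    return tokens


@dataclass(frozen=True)
class TokenVocabulary:
    """Immutable token inventory with index maps.

    Index layout: chemical tokens (sorted), then unknown, then the
    generator specials start/end/pad.  ``chem_size`` (chemical + unknown)
    is what a character-level predictor embeds; ``size`` is what a
    generator's softmax spans.
    """

    tokens: tuple[str, ...]
    two_char: tuple[str, ...] = TWO_CHAR_TOKENS
    index_of: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise VocabularyError("duplicate chemical tokens")
        specials = (UNK, START, END, PAD)
        if set(self.tokens) & set(specials):
            raise VocabularyError("chemical tokens collide with specials")
        full = tuple(self.tokens) + specials
        object.__setattr__(self, "index_of", {t: i for i, t in enumerate(full)})

    # -- sizes -------------------------------------------------------
    @property
    def chem_size(self) -> int:
        """Chemical tokens + unknown (predictor embedding rows)."""
        return len(self.tokens) + 1

    @property
    def size(self) -> int:
        """All tokens incl. specials (generator softmax width)."""
        return len(self.tokens) + 4

    @property
    def unk_index(self) -> int:
        return len(self.tokens)

    @property
    def start_index(self) -> int:
        return len(self.tokens) + 1

    @property
    def end_index(self) -> int:
        return len(self.tokens) + 2

    @property
    def pad_index(self) -> int:
        return len(self.tokens) + 3

    # -- construction --------------------------------------------------
    @classmethod
    def default(cls) -> "TokenVocabulary":
        return cls(tokens=tuple(sorted(DEFAULT_SMILES_TOKENS)))

    # -- mapping -------------------------------------------------------
    def tokenize(self, smiles: str) -> list[str]:
        return scan_tokens(smiles, self.two_char)

    def encode(self, smiles: str) -> list[int]:
        """Token indices; tokens outside the vocabulary map to unknown."""
        unk = self.unk_index
        return [self.index_of.get(t, unk) for t in self.tokenize(smiles)]

    def decode(self, indices: Iterable[int]) -> str:
        """Inverse of :meth:`encode` on strings without unknowns;
        specials are stripped."""
        full = tuple(self.tokens) + (UNK, START, END, PAD)
        drop = {self.start_index, self.end_index, self.pad_index}
        return "".join(full[i] for i in indices if i not in drop)

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps({"tokens": list(self.tokens),
                           "two_char": list(self.two_char)})

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        obj = json.loads(text)
        return cls(tokens=tuple(obj["tokens"]), two_char=tuple(obj["two_char"]))


def build_vocabulary(corpus: Iterable[str],
                     extra_tokens: Sequence[str] = (),
                     two_char: Sequence[str] = TWO_CHAR_TOKENS) -> TokenVocabulary:
    """Derive a vocabulary from every token observed in ``corpus``.

    The result is order-independent (tokens are sorted) and deterministic.
    Raises :class:`VocabularyError` if no token is observed.
    """
    seen: set[str] = set(extra_tokens)
    n = 0
    for smiles in corpus:
        n += 1
        seen.update(scan_tokens(smiles, two_char))
    if n == 0 or not seen:
        raise VocabularyError("empty corpus: no tokens observed")
    return TokenVocabulary(tokens=tuple(sorted(seen)), two_char=tuple(two_char))
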