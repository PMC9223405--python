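"""RDKit-backed SMILES validity, canonicalization, properties and file I/O.

Validity means the string parses *and* sanitizes (valence-checked) into a
molecule.  Properties: Crippen logP, benzene-ring count (aromatic
six-carbon ring substructure matches), molecular weight, and the
Ertl-Schuffenhauer synthetic-accessibility (SA) score in (1, 10) via the
RDKit contrib scorer.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Crippen, Descriptors

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, resolved via RDConfig)

_BENZENE = Chem.MolFromSmarts("c1ccccc1")

PROPERTY_NAMES = ("logP", "benzene_rings", "sa_score", "mol_wt")


class InvalidSmilesError(ValueError):
    """Raised when a property is requested for an unparsable string."""


@dataclass
class SmilesRecord:
    """One molecule: raw SMILES, optional canonical form, cached properties."""

    smiles: str
    canonical: Optional[str] = None
    properties: dict = field(default_factory=dict)


def _parse(smiles: str):
    if not isinstance(smiles, str) or not smiles:
        return None
    return Chem.MolFromSmiles(smiles)  # sanitizes by default


def check_validity(smiles: str) -> bool:
    """True iff the string parses and sanitizes into a molecule."""
    return _parse(smiles) is not None


def canonicalize(smiles: str) -> Optional[str]:
    """Canonical SMILES, or None for invalid input."""
    mol = _parse(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def compute_property(smiles: str, name: str) -> float:
    """Compute a named property of a valid SMILES string.

    Raises :class:`InvalidSmilesError` for unparsable input and
    ``ValueError`` for an unknown property name.
    """
    if name not in PROPERTY_NAMES:
        raise ValueError(f"unknown property {name!r}; expected one of {PROPERTY_NAMES}")
    mol = _parse(smiles)
    if mol is None:
        raise InvalidSmilesError(f"not a valid SMILES: {smiles!r}")
    if name == "logP":
        return float(Crippen.MolLogP(mol))
    if name == "benzene_rings":
        return float(len(mol.GetSubstructMatches(_BENZENE, uniquify=True)))
    if name == "mol_wt":
        return float(Descriptors.MolWt(mol))
    return float(sascorer.calculateScore(mol))


class SmilesFile(list):
    """List of :class:`SmilesRecord` plus skip accounting from reading."""

    def __init__(self, records=(), n_blank: int = 0, n_skipped: int = 0):
        super().__init__(records)
        self.n_blank = n_blank
        self.n_skipped = n_skipped

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self]


def read_smiles_file(path, validate: bool = False,
                     max_mol_wt: Optional[float] = None) -> SmilesFile:
    """Read a one-SMILES-per-line file.

    Blank lines are counted and dropped.  With ``validate=True``,
    unparsable lines are counted in ``n_skipped`` and dropped; with
    ``max_mol_wt`` set (implies validation), heavier molecules are
    skipped as well and valid records carry their ``mol_wt``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out = SmilesFile()
    filtering = validate or max_mol_wt is not None
    with open(path) as fh:
        for line in fh:
            s = line.strip().split()[0] if line.strip() else ""
            if not s:
                out.n_blank += 1
                continue
            if filtering:
                mol = _parse(s)
                if mol is None:
                    out.n_skipped += 1
                    continue
                rec = SmilesRecord(smiles=s, canonical=Chem.MolToSmiles(mol))
                if max_mol_wt is not None:
                    mw = float(Descriptors.MolWt(mol))
                    if mw > max_mol_wt:
                        out.n_skipped += 1
                        continue
                    rec.properties["mol_wt"] = mw
                out.append(rec)
            else:
                out.append(SmilesRecord(smiles=s))
    return out


def write_smiles_file(records: Iterable, path) -> int:
    """Write records (SmilesRecord or str) one SMILES per line; returns count."""
    n = 0
    with open(path, "w") as fh:
        for r in records:
            s = r.smiles if isinstance(r, SmilesRecord) else str(r)
            fh.write(s + "\n")
            n += 1
    return n
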