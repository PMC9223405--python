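"""Generator-quality metrics for a generated SMILES library.

The report mirrors the standard evaluation of unconditional molecular
generators: validity % (strings parsing as molecules), common % (valid
strings also present in the reference/training set — novelty is its
complement), property quartiles and mean over the valid molecules,
average string length in characters, and the median synthetic-
accessibility score.  Common % uses set semantics after canonicalizing
both sides (a ``canonicalize=False`` flag restores literal string
comparison); duplicates are retained everywhere else, and a uniqueness
percentage is reported alongside because libraries with collapsed
diversity can look deceptively valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import chem


def percent_valid(strings: Sequence[str]) -> float:
    """100 * (#valid / #strings)."""
    strings = list(strings)
    if not strings:
        raise ValueError("empty list of strings")
    return 100.0 * float(np.mean([chem.check_validity(s) for s in strings]))


def _canon_set(strings: Sequence[str], canonicalize: bool) -> set:
    if not canonicalize:
        return set(strings)
    out = set()
    for s in strings:
        c = chem.canonicalize(s)
        if c is not None:
            out.add(c)
    return out


def percent_common(generated: Sequence[str], reference: Sequence[str],
                   canonicalize: bool = True) -> float:
    """Overlap of the generated set with the reference set, in %.

    Set semantics: 100 * |canon(gen) ∩ canon(ref)| / |canon(gen)|.
    """
    generated, reference = list(generated), list(reference)
    if not generated or not reference:
        raise ValueError("generated and reference must be non-empty")
    gset = _canon_set(generated, canonicalize)
    rset = _canon_set(reference, canonicalize)
    if not gset:
        raise ValueError("no usable generated strings after canonicalization")
    return 100.0 * len(gset & rset) / len(gset)


def property_quartiles(values: Sequence[float]):
    """(q1, q2, q3, mean) with linear (type-7) quartile interpolation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4 or not np.all(np.isfinite(arr)):
        raise ValueError("need at least 4 finite values")
    q1, q2, q3 = np.quantile(arr, [0.25, 0.5, 0.75], method="linear")
    return float(q1), float(q2), float(q3), float(arr.mean())


def average_length(strings: Sequence[str], mode: str = "chars") -> float:
    """Mean length in raw characters (default) or in SMILES tokens."""
    strings = list(strings)
    if not strings:
        raise ValueError("empty list of strings")
    if mode == "chars":
        return float(np.mean([len(s) for s in strings]))
    if mode == "tokens":
        from .tokenizer import scan_tokens
        return float(np.mean([len(scan_tokens(s)) for s in strings]))
    raise ValueError("mode must be 'chars' or 'tokens'")


@dataclass
class EvaluationReport:
    """Metrics of one generated library against a reference set."""

    n_generated: int
    valid_pct: float
    common_pct: float
    unique_pct: float
    q1: float
    q2: float
    q3: float
    mean: float
    avg_length: float
    median_sa: Optional[float]
    property_name: str
    property_values: list = field(default_factory=list, repr=False)

    def to_dict(self, include_values: bool = True) -> dict:
        d = asdict(self)
        if not include_values:
            d.pop("property_values")
        return d


def build_report(generated: Sequence[str], reference: Sequence[str],
                 property_name: str = "logP",
                 canonicalize: bool = True,
                 length_mode: str = "chars") -> EvaluationReport:
    """Full evaluation; invalid strings are excluded before property
    statistics (they still count against validity %)."""
    generated = list(generated)
    if not generated:
        raise ValueError("empty generated library")
    valid = [s for s in generated if chem.check_validity(s)]
    valid_pct = 100.0 * len(valid) / len(generated)
    common = percent_common(valid, reference, canonicalize) if valid else 0.0
    unique = (100.0 * len(_canon_set(valid, canonicalize)) / len(valid)
              if valid else 0.0)
    if len(valid) >= 4:
        values = [chem.compute_property(s, property_name) for s in valid]
        q1, q2, q3, mean = property_quartiles(values)
    else:
        values, q1, q2, q3, mean = [], np.nan, np.nan, np.nan, np.nan
    median_sa = (float(np.median([chem.compute_property(s, "sa_score")
                                  for s in valid])) if valid else None)
    return EvaluationReport(
        n_generated=len(generated),
        valid_pct=valid_pct,
        common_pct=common,
        unique_pct=unique,
        q1=q1, q2=q2, q3=q3, mean=mean,
        avg_length=average_length(generated, length_mode),
        median_sa=median_sa,
        property_name=property_name,
        property_values=[float(v) for v in values],
    )


def export_report(report: EvaluationReport, path) -> None:
    """JSON (.json) or a one-row CSV table (anything else)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    else:
        pd.DataFrame([report.to_dict(include_values=False)]).to_csv(
            path, index=False)


def kde_grid(values: Sequence[float], bandwidth: float = 0.25,
             n_grid: int = 256):
    """Fixed-bandwidth Gaussian KDE evaluated on a regular grid."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    lo, hi = v.min() - 3 * bandwidth, v.max() + 3 * bandwidth
    grid = np.linspace(lo, hi, n_grid)
    z = (grid[:, None] - v[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * bandwidth *
                                               np.sqrt(2 * np.pi))
    return grid, dens


def export_density(values: Sequence[float], path,
                   bandwidth: float = 0.25) -> None:
    """Raw values plus a KDE grid for density plotting.

    CSV rows carry ``section`` = 'raw' (x = value) or 'kde'
    (x = grid point, y = density); JSON output keeps three arrays.
    """
    values = [float(v) for v in values]
    grid, dens = kde_grid(values, bandwidth)
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump({"values": values, "grid": grid.tolist(),
                       "density": dens.tolist(),
                       "bandwidth": bandwidth}, fh)
        return
    raw = pd.DataFrame({"section": "raw", "x": values, "y": np.nan})
    kde = pd.DataFrame({"section": "kde", "x": grid, "y": dens})
    pd.concat([raw, kde], ignore_index=True).to_csv(path, index=False)
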