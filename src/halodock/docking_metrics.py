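"""Docking-energy bookkeeping: Ki conversion, ranking, halogen-series trend.

The inhibition constant follows from the docking free energy through the
thermodynamic relation Ki = exp(dG / RT) with R in kcal/(mol K); more
negative dG means tighter (smaller) Ki.  Temperature defaults to 298.15 K
and is recorded with every converted value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

#: Molar gas constant, kcal mol^-1 K^-1 (CODATA).
GAS_CONSTANT_KCAL = 1.98720425864e-3

DEFAULT_TEMPERATURE_K = 298.15

HALOGEN_ORDER = ("F", "Cl", "Br", "I")

_UNIT_SCALE = (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12))


@dataclass(frozen=True)
class DockingRecord:
    compound_id: str
    binding_energy: float  # kcal/mol, negative = favorable
    halogen: str = "none"  # none | F | Cl | Br | I
    n_substitutions: int = 0


def ki_from_binding_energy(
    dg: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Inhibition constant (mol/L) from a docking free energy (kcal/mol)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return math.exp(dg / (GAS_CONSTANT_KCAL * temperature))


def binding_energy_from_ki(
    ki_molar: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Inverse of :func:`ki_from_binding_energy` (log inversion)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if ki_molar <= 0:
        raise ValueError(f"Ki must be positive, got {ki_molar}")
    return math.log(ki_molar) * GAS_CONSTANT_KCAL * temperature


def format_ki(ki_molar: float) -> str:
    """Auto-scaled human-readable Ki (M/mM/uM/nM/pM)."""
    for unit, scale in _UNIT_SCALE:
        if ki_molar >= scale or unit == "pM":
            return f"{ki_molar / scale:.2f} {unit}"
    return f"{ki_molar:.3e} M"


def rank_ligands(records: Sequence[DockingRecord]) -> list[DockingRecord]:
    """Order by binding energy ascending (most negative = best), then id.

    The output is a permutation of the input; ties break lexicographically on
    compound_id so ranking is deterministic.
    """
    if not records:
        raise ValueError("cannot rank an empty set of docking records")
    return sorted(records, key=lambda r: (r.binding_energy, r.compound_id))


@dataclass(frozen=True)
class HalogenTrend:
    means: dict[str, float]  # halogen class -> mean dG (kcal/mol)
    ordered: bool | None  # None when a class is missing
    missing: tuple[str, ...] = ()


def halogen_trend(records: Sequence[DockingRecord]) -> HalogenTrend:
    """Mean binding energy per halogen class and the F>Cl>Br>I ordering flag.

    The flag is True when the signed means strictly decrease from F to I
    (iodine most favorable).  With any class absent the flag is undefined
    (None) and the missing classes are reported.
    """
    by_class: dict[str, list[float]] = {h: [] for h in HALOGEN_ORDER}
    for r in records:
        if r.halogen in by_class:
            by_class[r.halogen].append(r.binding_energy)
    means = {h: sum(v) / len(v) for h, v in by_class.items() if v}
    missing = tuple(h for h in HALOGEN_ORDER if h not in means)
    if missing:
        return HalogenTrend(means=means, ordered=None, missing=missing)
    vals = [means[h] for h in HALOGEN_ORDER]
    ordered = all(a > b for a, b in zip(vals, vals[1:]))
    return HalogenTrend(means=means, ordered=ordered)


def read_docking_tsv(source) -> list[DockingRecord]:
    """Read docking records from a TSV with columns
    compound_id / binding_energy [/ halogen / n_substitutions]."""
    df = pd.read_csv(source, sep="\t", comment="#")
    if not {"compound_id", "binding_energy"} <= set(df.columns):
        raise ValueError("docking TSV needs compound_id and binding_energy columns")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            DockingRecord(
                compound_id=str(r.compound_id),
                binding_energy=float(r.binding_energy),
                halogen=str(getattr(r, "halogen", "none")),
                n_substitutions=int(getattr(r, "n_substitutions", 0)),
            )
        )
    return out
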