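"""Global conceptual-DFT reactivity descriptors from frontier-orbital energies.

Within Koopmans' approximation the vertical ionization energy and electron
affinity of a closed-shell molecule are read off the frontier-orbital
eigenvalues, ``IE = -eps_HOMO`` and ``EA = -eps_LUMO``.  The finite-difference
global descriptors then follow:

    eta      = (IE - EA) / 2         global hardness          (eV)
    S        = 1 / (IE - EA)         global softness          (1/eV)
    mu       = (eps_HOMO + eps_LUMO) / 2   chemical potential (eV)
    chi      = -mu                   electronegativity        (eV)
    omega    = mu**2 / (2 * eta)     electrophilicity index   (eV)
    gap      = eps_LUMO - eps_HOMO   HOMO-LUMO gap            (eV)

All energies are in electronvolts.  Orbital energies computed in hartree must
be pre-converted with :data:`HARTREE_TO_EV`.  Text output is rounded to two
decimals (the convention of the descriptor tables this module materializes);
full precision is kept internally.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

#: Conversion factor from hartree to electronvolt.
HARTREE_TO_EV = 27.211386

#: Column order of the descriptor table (after compound_id, homo_ev, lumo_ev).
DESCRIPTOR_COLUMNS = ("ie", "ea", "chi", "mu", "eta", "softness", "omega", "gap")


@dataclass(frozen=True)
class OrbitalEnergies:
    """HOMO/LUMO eigenvalues of one compound, in eV."""

    compound_id: str
    homo_ev: float
    lumo_ev: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.homo_ev) and math.isfinite(self.lumo_ev)):
            raise ValueError(f"{self.compound_id}: orbital energies must be finite")
        if self.lumo_ev <= self.homo_ev:
            raise ValueError(
                f"{self.compound_id}: invalid orbital ordering "
                f"(LUMO {self.lumo_ev} eV must lie above HOMO {self.homo_ev} eV)"
            )


@dataclass(frozen=True)
class ReactivityDescriptors:
    """Global reactivity descriptors of one compound.

    ``ie``, ``ea``, ``chi``, ``mu``, ``eta``, ``omega`` and ``gap`` are in eV;
    ``softness`` is in 1/eV.
    """

    ie: float
    ea: float
    chi: float
    mu: float
    eta: float
    softness: float
    omega: float
    gap: float


def descriptors_from_orbitals(orbitals: OrbitalEnergies) -> ReactivityDescriptors:
    """Compute the full descriptor set from HOMO/LUMO eigenvalues.

    Raises ``ValueError`` for a degenerate (zero) or inverted gap, for which
    softness is undefined.
    """
    homo, lumo = orbitals.homo_ev, orbitals.lumo_ev
    ie = -homo
    ea = -lumo
    eta = (lumo - homo) / 2.0
    mu = (lumo + homo) / 2.0
    return ReactivityDescriptors(
        ie=ie,
        ea=ea,
        chi=-mu,
        mu=mu,
        eta=eta,
        softness=1.0 / (ie - ea),
        omega=mu * mu / (2.0 * eta),
        gap=lumo - homo,
    )


def descriptors_from_ie_ea(ie: float, ea: float, compound_id: str = "") -> ReactivityDescriptors:
    """Compute descriptors from an (IE, EA) pair in eV.

    Equivalent to :func:`descriptors_from_orbitals` at ``homo_ev=-ie``,
    ``lumo_ev=-ea``.  Rejects ``ie <= ea`` (softness undefined).
    """
    return descriptors_from_orbitals(
        OrbitalEnergies(compound_id=compound_id or "ie_ea", homo_ev=-ie, lumo_ev=-ea)
    )


def descriptor_table(orbitals: Sequence[OrbitalEnergies]) -> pd.DataFrame:
    """Materialize a per-compound descriptor table.

    One row per compound, in input order, with columns ``compound_id``,
    ``homo_ev``, ``lumo_ev`` followed by :data:`DESCRIPTOR_COLUMNS`.
    Duplicate compound ids are rejected.
    """
    ids = [o.compound_id for o in orbitals]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound_id(s): {', '.join(dupes)}")
    rows = []
    for o in orbitals:
        d = descriptors_from_orbitals(o)
        rows.append(
            {"compound_id": o.compound_id, "homo_ev": o.homo_ev, "lumo_ev": o.lumo_ev}
            | {c: getattr(d, c) for c in DESCRIPTOR_COLUMNS}
        )
    return pd.DataFrame(
        rows, columns=["compound_id", "homo_ev", "lumo_ev", *DESCRIPTOR_COLUMNS]
    )


def read_orbitals_tsv(source) -> list[OrbitalEnergies]:
    """Read orbital energies from TSV with columns compound_id/homo_ev/lumo_ev.

    ``source`` is a path or file-like object; ``#`` comment lines are ignored,
    a header is required.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    required = {"compound_id", "homo_ev", "lumo_ev"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"orbital TSV missing column(s): {', '.join(sorted(missing))}")
    return [
        OrbitalEnergies(str(r.compound_id), float(r.homo_ev), float(r.lumo_ev))
        for r in df.itertuples(index=False)
    ]


def write_descriptor_tsv(table: pd.DataFrame, dest) -> None:
    """Write a descriptor table as TSV, numeric values rounded to 2 decimals."""
    out = table.copy()
    for c in out.columns:
        if c != "compound_id":
            out[c] = out[c].map(lambda v: f"{v:.2f}")
    out.to_csv(dest, sep="\t", index=False)


def format_descriptor_tsv(table: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_descriptor_tsv(table, buf)
    return buf.getvalue()
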