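"""Noncovalent-interaction detection for docked protein-ligand complexes.

Three contact classes are detected and attributed per residue:

* **halogen** — the operational docking-survey criterion: a receptor hydrogen
  atom strictly closer than 4 A to a ligand halogen (F, Cl, Br, I).  This is
  deliberately the protein-H-to-halogen distance rule, not the crystallographic
  sigma-hole definition; an optional ``xb_mode="sigma-hole"`` variant adds a
  C-X...H angle requirement (>= 140 deg) for comparison and is OFF by default.
* **hbond** — donor/acceptor heavy atoms (N, O, S) within ``hbond_dmax`` with,
  when explicit hydrogens are present on the donor, a D-H...A angle of at
  least ``hbond_angle_min``.
* **pi** — ring-ring stacking (``pi_pi``: centroid distance <= ``pi_dcc_max``
  and interplanar angle parallel within ``pi_tilt_max`` or T-shaped within
  [90 - tilt, 90]) and ring-alkyl contacts (``pi_alkyl``: an sp3 carbon within
  ``pi_dcc_max`` of a ring centroid).

All detectors are exact all-pairs scans; no spatial indexing is used, so
results are reproducible against a brute-force oracle by construction.
Contacts are sorted by (kind, distance, resseq, serial) so reports are
byte-stable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .structure_io import (
    AtomRecord,
    ComplexStructure,
    HALOGEN_ELEMENTS,
    ring_centroid_normal,
)

ACCEPTOR_ELEMENTS = {"N", "O", "S"}

#: Canonical side-chain ring atom names of aromatic residues.
AROMATIC_RESIDUE_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "TRP": (("CG", "CD1", "NE1", "CE2", "CD2"), ("CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2")),
}

#: Residues whose side-chain carbons count as alkyl partners.
ALIPHATIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "MET"}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class NoReceptorHydrogensWarning(UserWarning):
    """Receptor carries no explicit hydrogens; halogen contacts are undetectable."""


@dataclass(frozen=True)
class ProfilerConfig:
    """Geometric criteria used by the detectors (distances in A, angles in deg)."""

    halogen_cutoff: float = 4.0
    xb_mode: str = "hydrogen"  # or "sigma-hole"
    xb_sigma_angle_min: float = 140.0
    hbond_dmax: float = 3.5
    hbond_angle_min: float = 120.0
    pi_dcc_max: float = 5.5
    pi_tilt_max: float = 30.0


@dataclass(frozen=True)
class Contact:
    kind: str  # hbond | pi_pi | pi_alkyl | halogen
    receptor_atom: AtomRecord | None
    ligand_atom: AtomRecord | None
    ring_id: int | None
    distance: float
    angle: float | None
    residue_label: str

    def _sort_key(self):
        resseq = self.receptor_atom.resseq if self.receptor_atom else -1
        serial = self.receptor_atom.serial if self.receptor_atom else -1
        return (self.kind, self.distance, resseq, serial)


@dataclass
class InteractionReport:
    contacts: list[Contact]
    counts: dict[str, int]
    residues: dict[str, list[str]]
    criteria: ProfilerConfig
    warnings: list[str] = field(default_factory=list)

    @property
    def total_contacts(self) -> int:
        """Number of unique contacts across all classes."""
        return len(self.contacts)

    @property
    def total_residue_pairs(self) -> int:
        """Number of (kind, residue) attribution pairs — the alternative tally."""
        return sum(len(v) for v in self.residues.values())

    def to_dict(self) -> dict:
        return {
            "criteria": asdict(self.criteria),
            "counts": dict(self.counts),
            "totals": {
                "contacts": self.total_contacts,
                "residue_pairs": self.total_residue_pairs,
            },
            "contacts": [
                {
                    "kind": c.kind,
                    "residue": c.residue_label,
                    "receptor_atom": c.receptor_atom.name if c.receptor_atom else None,
                    "ligand_atom": c.ligand_atom.name if c.ligand_atom else None,
                    "ring_id": c.ring_id,
                    "distance": round(c.distance, 3),
                    "angle": None if c.angle is None else round(c.angle, 1),
                }
                for c in self.contacts
            ],
            "residues": {k: list(v) for k, v in self.residues.items()},
            "warnings": list(self.warnings),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_tsv(self) -> str:
        lines = ["kind\tresidue\treceptor_atom\tligand_atom\tdistance\tangle"]
        for c in self.contacts:
            ang = "" if c.angle is None else f"{c.angle:.1f}"
            lines.append(
                f"{c.kind}\t{c.residue_label}\t"
                f"{c.receptor_atom.name if c.receptor_atom else ''}\t"
                f"{c.ligand_atom.name if c.ligand_atom else ''}\t"
                f"{c.distance:.3f}\t{ang}"
            )
        return "\n".join(lines) + "\n"


def _dist(a: AtomRecord, b: AtomRecord) -> float:
    return float(np.linalg.norm(a.coords - b.coords))


def _angle_deg(p: np.ndarray, vertex: np.ndarray, q: np.ndarray) -> float:
    u, v = p - vertex, q - vertex
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _attached_hydrogens(atoms: Sequence[AtomRecord], idx: int) -> list[AtomRecord]:
    """Hydrogens within covalent range (1.2 A) of a heavy atom, same atom set."""
    heavy = atoms[idx]
    return [
        a for a in atoms
        if a.element == "H" and a is not heavy and _dist(a, heavy) <= 1.2
    ]


def find_halogen_contacts(
    cplx: ComplexStructure,
    cutoff: float = 4.0,
    xb_mode: str = "hydrogen",
    sigma_angle_min: float = 140.0,
) -> list[Contact]:
    """Receptor-H to ligand-halogen contacts at strictly < ``cutoff`` A.

    With ``xb_mode="sigma-hole"`` a C-X...H angle >= ``sigma_angle_min`` is
    additionally required (the halogen's bonded carbon defines the sigma-hole
    axis).  Emits :class:`NoReceptorHydrogensWarning` when the receptor has no
    explicit hydrogens (result is then trivially empty, never silently).
    """
    halogens = [(i, a) for i, a in enumerate(cplx.ligand) if a.element in HALOGEN_ELEMENTS]
    if not halogens:
        return []
    hydrogens = [a for a in cplx.receptor if a.element == "H"]
    if not hydrogens:
        warnings.warn(
            "receptor contains no explicit hydrogens; halogen-contact "
            "detection (protein-H...X) cannot find anything",
            NoReceptorHydrogensWarning,
            stacklevel=2,
        )
        return []
    bonded: dict[int, list[int]] = {}
    if xb_mode == "sigma-hole":
        for i, j in cplx.ligand_bonds:
            bonded.setdefault(i, []).append(j)
            bonded.setdefault(j, []).append(i)
    contacts = []
    for h in hydrogens:
        for li, x in halogens:
            d = _dist(h, x)
            if d >= cutoff:
                continue
            angle = None
            if xb_mode == "sigma-hole":
                carbons = [k for k in bonded.get(li, ()) if cplx.ligand[k].element != "H"]
                if carbons:
                    angle = _angle_deg(cplx.ligand[carbons[0]].coords, x.coords, h.coords)
                    if angle < sigma_angle_min:
                        continue
            contacts.append(
                Contact("halogen", h, x, None, d, angle, h.residue_label)
            )
    contacts.sort(key=lambda c: (c.distance, c.receptor_atom.resseq, c.receptor_atom.serial))
    return contacts


def find_hydrogen_bonds(
    cplx: ComplexStructure, d_max: float = 3.5, angle_min: float = 120.0
) -> list[Contact]:
    """Hydrogen bonds between receptor and ligand N/O/S atoms.

    A donor-acceptor pair qualifies when the heavy-atom distance is at most
    ``d_max`` and, when either heavy atom carries explicit hydrogens, the best
    D-H...A angle is at least ``angle_min``.  Pairs without any explicit
    hydrogen pass on distance alone (polar hydrogens are often absent from
    docked files).  Each unordered heavy-atom pair is reported once.
    """
    rec_polar = [(i, a) for i, a in enumerate(cplx.receptor) if a.element in ACCEPTOR_ELEMENTS]
    lig_polar = [(i, a) for i, a in enumerate(cplx.ligand) if a.element in ACCEPTOR_ELEMENTS]
    contacts = []
    for ri, r in rec_polar:
        r_hyds = _attached_hydrogens(cplx.receptor, ri)
        for li, l in lig_polar:
            d = _dist(r, l)
            if d > d_max:
                continue
            l_hyds = _attached_hydrogens(cplx.ligand, li)
            best_angle = None
            if r_hyds or l_hyds:
                angles = [_angle_deg(r.coords, h.coords, l.coords) for h in r_hyds]
                angles += [_angle_deg(l.coords, h.coords, r.coords) for h in l_hyds]
                best_angle = max(angles)
                if best_angle < angle_min:
                    continue
            contacts.append(Contact("hbond", r, l, None, d, best_angle, r.residue_label))
    contacts.sort(key=lambda c: (c.distance, c.receptor_atom.resseq, c.receptor_atom.serial))
    return contacts


def receptor_aromatic_rings(receptor: Sequence[AtomRecord]) -> list[list[int]]:
    """Indices of complete aromatic side-chain rings, grouped by residue."""
    by_res: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, a in enumerate(receptor):
        if a.resname in AROMATIC_RESIDUE_RINGS:
            by_res.setdefault((a.chain, a.resseq, a.resname), {})[a.name] = i
    rings: list[list[int]] = []
    for (chain, resseq, resname), atoms in sorted(by_res.items()):
        for names in AROMATIC_RESIDUE_RINGS[resname]:
            if all(n in atoms for n in names):
                rings.append([atoms[n] for n in names])
    return rings


def _is_receptor_alkyl_carbon(atom: AtomRecord) -> bool:
    return (
        atom.element == "C"
        and atom.resname in ALIPHATIC_RESIDUES
        and atom.name not in _BACKBONE_ATOMS
    )


def _ligand_sp3_carbons(cplx: ComplexStructure) -> list[int]:
    """Ligand carbons with >= 3 bonded hydrogens (methyl-like alkyl probes)."""
    h_count: dict[int, int] = {}
    for i, j in cplx.ligand_bonds:
        for a, b in ((i, j), (j, i)):
            if cplx.ligand[b].element == "H" and cplx.ligand[a].element == "C":
                h_count[a] = h_count.get(a, 0) + 1
    return [i for i, n in h_count.items() if n >= 3]


def find_pi_interactions(
    cplx: ComplexStructure, dcc_max: float = 5.5, tilt_max: float = 30.0
) -> list[Contact]:
    """Ring-ring (pi_pi) and ring-alkyl (pi_alkyl) contacts.

    pi_pi: ligand-ring / receptor-ring centroid distance <= ``dcc_max`` and
    interplanar angle either <= ``tilt_max`` (parallel) or within
    [90 - tilt_max, 90] (T-shaped).  pi_alkyl: an sp3 carbon (receptor
    aliphatic side chain, or ligand C bearing >= 3 H) within ``dcc_max`` of
    the opposing ring centroid.  One contact per (ring, partner).
    """
    contacts: list[Contact] = []
    lig_rings = [ring_centroid_normal(cplx.ligand, r) for r in cplx.ligand_rings]
    rec_ring_idx = receptor_aromatic_rings(cplx.receptor)
    rec_rings = [ring_centroid_normal(cplx.receptor, r) for r in rec_ring_idx]

    for rid, (rc, rn) in enumerate(rec_rings):
        anchor = cplx.receptor[rec_ring_idx[rid][0]]
        for lid, (lc, ln) in enumerate(lig_rings):
            d = float(np.linalg.norm(rc - lc))
            if d > dcc_max:
                continue
            cosang = abs(float(np.dot(rn, ln)))
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))  # folded to [0, 90]
            if angle <= tilt_max or angle >= 90.0 - tilt_max:
                contacts.append(
                    Contact("pi_pi", anchor, None, lid, d, angle, anchor.residue_label)
                )

    for atom in cplx.receptor:
        if not _is_receptor_alkyl_carbon(atom):
            continue
        for lid, (lc, _) in enumerate(lig_rings):
            d = float(np.linalg.norm(atom.coords - lc))
            if d <= dcc_max:
                contacts.append(
                    Contact("pi_alkyl", atom, None, lid, d, None, atom.residue_label)
                )

    sp3 = _ligand_sp3_carbons(cplx)
    for rid, (rc, _) in enumerate(rec_rings):
        anchor = cplx.receptor[rec_ring_idx[rid][0]]
        for li in sp3:
            d = float(np.linalg.norm(cplx.ligand[li].coords - rc))
            if d <= dcc_max:
                contacts.append(
                    Contact(
                        "pi_alkyl", anchor, cplx.ligand[li], None, d, None,
                        anchor.residue_label,
                    )
                )
    contacts.sort(key=Contact._sort_key)
    return contacts


def profile_complex(
    cplx: ComplexStructure, config: ProfilerConfig | None = None
) -> InteractionReport:
    """Run all three detectors and assemble a per-residue interaction report."""
    if not cplx.ligand:
        raise ValueError("complex has an empty ligand; nothing to profile")
    cfg = config or ProfilerConfig()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", NoReceptorHydrogensWarning)
        halogen = find_halogen_contacts(
            cplx, cfg.halogen_cutoff, cfg.xb_mode, cfg.xb_sigma_angle_min
        )
        caught = [str(w.message) for w in wlist if issubclass(w.category, NoReceptorHydrogensWarning)]
    hbond = find_hydrogen_bonds(cplx, cfg.hbond_dmax, cfg.hbond_angle_min)
    pi = find_pi_interactions(cplx, cfg.pi_dcc_max, cfg.pi_tilt_max)
    contacts = sorted(halogen + hbond + pi, key=Contact._sort_key)
    kinds = ("halogen", "hbond", "pi_pi", "pi_alkyl")
    counts = {k: sum(1 for c in contacts if c.kind == k) for k in kinds}
    residues: dict[str, list[str]] = {}
    for k in kinds:
        seen: list[str] = []
        for c in contacts:
            if c.kind == k and c.residue_label not in seen:
                seen.append(c.residue_label)
        residues[k] = seen
    return InteractionReport(
        contacts=contacts, counts=counts, residues=residues, criteria=cfg,
        warnings=caught,
    )
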