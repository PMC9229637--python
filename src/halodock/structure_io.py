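"""Fixed-column PDB reading/writing and ligand chemical annotation.

Parses ATOM/HETATM records of a protein-ligand complex, splits receptor
(polymer ATOM records) from ligand (HETATM records of a chosen residue name),
drops waters, infers elements when the element column is absent, and derives
the ligand bond graph and aromatic rings needed for interaction profiling.

Coordinates are in angstroms; residue numbering is kept exactly as in the
file.  Only the first MODEL of a multi-model file is read here; trajectories
have a dedicated reader in :mod:`halodock.trajectory_metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

WATER_RESNAMES = {"HOH", "WAT"}

#: Single-bond covalent radii (angstrom), Cordero et al. values.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}

KNOWN_ELEMENTS = set(COVALENT_RADII)

#: Two-letter element symbols we recognize in atom-name columns 13-14.
_TWO_LETTER = {"CL": "Cl", "BR": "Br", "FE": "Fe", "ZN": "Zn", "MG": "Mg",
               "MN": "Mn", "NA": "Na", "CA": "Ca", "SE": "Se"}

HALOGEN_ELEMENTS = {"F", "Cl", "Br", "I"}

#: Default tolerance factor on the covalent-radius sum for bond inference.
BOND_TOLERANCE = 1.3

#: Max deviation (angstrom) from the best-fit plane for an aromatic ring.
PLANARITY_TOLERANCE = 0.15


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record."""

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    xyz: tuple[float, float, float]
    element: str
    is_hetatm: bool = False
    altloc: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    @property
    def residue_label(self) -> str:
        """Residue label in 'Val143' style."""
        return self.resname.capitalize() + str(self.resseq)


@dataclass
class ComplexStructure:
    """A receptor/ligand split of a complex with ligand chemistry annotated."""

    receptor: list[AtomRecord]
    ligand: list[AtomRecord]
    ligand_bonds: list[tuple[int, int]] = field(default_factory=list)
    ligand_rings: list[frozenset[int]] = field(default_factory=list)

    def annotate_ligand(self) -> None:
        """(Re)derive ligand bonds and aromatic rings from coordinates."""
        self.ligand_bonds = infer_ligand_bonds(self.ligand)
        self.ligand_rings = perceive_aromatic_rings(self.ligand, self.ligand_bonds)


def infer_element(name_field: str, resname: str) -> str:
    """Infer an element symbol from the PDB atom-name columns (13-16).

    Rule: if columns 13-14 spell a recognized two-letter symbol (e.g. ``CL``,
    ``BR`` left-justified at column 13, the PDB convention for two-letter
    elements), use it; otherwise the first alphabetic character after
    stripping digits and whitespace.  A name like ``" CA "`` in an amino acid
    is carbon, not calcium, because the symbol does not start in column 13.
    """
    two = name_field[:2].strip().upper()
    if len(name_field) >= 2 and not name_field[0].isspace() and not name_field[0].isdigit():
        if two in _TWO_LETTER:
            return _TWO_LETTER[two]
    for ch in name_field:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name_field!r}")


def _parse_atom_line(line: str, lineno: int) -> AtomRecord:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed coordinate field: {line.rstrip()!r}") from exc
    if not all(np.isfinite([x, y, z])):
        raise ValueError(f"line {lineno}: non-finite coordinates")
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    name_field = line[12:16]
    elem_field = line[76:78].strip() if len(line) >= 78 else ""
    if elem_field:
        element = elem_field.capitalize()
    else:
        element = infer_element(name_field, line[17:20].strip())
    try:
        resseq = int(line[22:26])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed residue number: {line.rstrip()!r}") from exc
    return AtomRecord(
        serial=serial,
        name=name_field.strip(),
        resname=line[17:20].strip(),
        chain=line[21].strip() or "A",
        resseq=resseq,
        xyz=(x, y, z),
        element=element,
        is_hetatm=line.startswith("HETATM"),
        altloc=line[16].strip(),
    )


def parse_pdb_atoms(pdb_text: str, first_model_only: bool = True) -> list[AtomRecord]:
    """Parse ATOM/HETATM records, keeping altloc 'A' or blank only."""
    atoms: list[AtomRecord] = []
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec == "ENDMDL" and first_model_only:
            break
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        atom = _parse_atom_line(line, lineno)
        if atom.altloc not in ("", "A"):
            continue
        atoms.append(atom)
    return atoms


def read_complex(pdb_text: str, ligand_resname: str) -> ComplexStructure:
    """Split a PDB complex into receptor and the ligand residue ``ligand_resname``.

    Receptor = polymer ATOM records; ligand = HETATM records whose residue
    name matches.  Waters (HOH/WAT) are dropped from both sets.  Raises
    ``ValueError`` when the text contains no atoms or when no HETATM residue
    matches (the error names the residue names that are present).
    """
    atoms = parse_pdb_atoms(pdb_text)
    if not atoms:
        raise ValueError("no ATOM/HETATM records found")
    receptor = [a for a in atoms if not a.is_hetatm and a.resname not in WATER_RESNAMES]
    het = [a for a in atoms if a.is_hetatm and a.resname not in WATER_RESNAMES]
    ligand = [a for a in het if a.resname == ligand_resname]
    if not ligand:
        available = sorted({a.resname for a in het}) or ["<none>"]
        raise ValueError(
            f"no HETATM residue named {ligand_resname!r}; "
            f"available: {', '.join(available)}"
        )
    cplx = ComplexStructure(receptor=receptor, ligand=ligand)
    cplx.annotate_ligand()
    return cplx


def infer_ligand_bonds(
    ligand: Sequence[AtomRecord], tolerance: float = BOND_TOLERANCE
) -> list[tuple[int, int]]:
    """Infer covalent bonds from interatomic distances (all-pairs scan).

    Heavy-heavy pairs bond when their distance is at most ``tolerance`` times
    the covalent-radius sum; a hydrogen bonds to a heavy atom within 1.2 A.
    Returns symmetric pairs as sorted (i, j) index tuples, no self-bonds.
    """
    bonds: list[tuple[int, int]] = []
    n = len(ligand)
    coords = np.array([a.coords for a in ligand]) if n else np.empty((0, 3))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ligand[i], ligand[j]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if a.element == "H" and b.element == "H":
                continue
            if a.element == "H" or b.element == "H":
                if d <= 1.2:
                    bonds.append((i, j))
                continue
            ra = COVALENT_RADII.get(a.element, 0.77)
            rb = COVALENT_RADII.get(b.element, 0.77)
            if d <= tolerance * (ra + rb):
                bonds.append((i, j))
    return bonds


def plane_deviation(coords: np.ndarray) -> float:
    """Max distance of points from their best-fit (least-squares) plane."""
    centered = coords - coords.mean(axis=0)
    # smallest right singular vector = plane normal
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return float(np.abs(centered @ normal).max())


def perceive_aromatic_rings(
    ligand: Sequence[AtomRecord],
    bonds: Iterable[tuple[int, int]],
    planarity_tol: float = PLANARITY_TOLERANCE,
) -> list[frozenset[int]]:
    """Find planar 5- and 6-membered rings of sp2-eligible atoms (C, N, O, S).

    A cycle counts as aromatic-like when every member is C/N/O/S and no member
    deviates more than ``planarity_tol`` from the ring's best-fit plane.  Each
    ring (as an atom set) is reported once; fused systems yield one ring per
    constituent cycle.
    """
    eligible = {i for i, a in enumerate(ligand) if a.element in {"C", "N", "O", "S"}}
    g = nx.Graph(b for b in bonds if b[0] in eligible and b[1] in eligible)
    rings: list[frozenset[int]] = []
    seen: set[frozenset[int]] = set()
    for cycle in nx.simple_cycles(g, length_bound=6):
        if len(cycle) not in (5, 6):
            continue
        key = frozenset(cycle)
        if key in seen:
            continue
        seen.add(key)
        coords = np.array([ligand[i].coords for i in cycle])
        if plane_deviation(coords) <= planarity_tol:
            rings.append(key)
    rings.sort(key=lambda r: sorted(r))
    return rings


def ring_centroid_normal(atoms: Sequence[AtomRecord], ring: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a ring given member atom indices."""
    coords = np.array([atoms[i].coords for i in ring])
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    normal = vt[-1]
    return centroid, normal / np.linalg.norm(normal)


def format_pdb_atom(atom: AtomRecord) -> str:
    rec = "HETATM" if atom.is_hetatm else "ATOM  "
    name = atom.name
    # PDB convention: one-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.xyz
    return (
        f"{rec}{atom.serial:>5} {name:<4}{atom.altloc or ' '}{atom.resname:>3} "
        f"{atom.chain:1}{atom.resseq:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2}"
    )


def write_pdb(
    receptor: Sequence[AtomRecord],
    ligand: Sequence[AtomRecord] = (),
    remark: str | None = None,
) -> str:
    """Serialize atoms back to fixed-column PDB text."""
    lines: list[str] = []
    if remark:
        lines.append(f"REMARK   1 {remark}")
    for a in receptor:
        lines.append(format_pdb_atom(a))
    if receptor:
        lines.append("TER")
    for a in ligand:
        lines.append(format_pdb_atom(a))
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_complex_pdb(cplx: ComplexStructure, remark: str | None = None) -> str:
    return write_pdb(cplx.receptor, cplx.ligand, remark=remark)
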