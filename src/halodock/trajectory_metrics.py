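"""Superposition RMSD (Kabsch) and trajectory RMSD/RMSF stability metrics.

The Kabsch algorithm gives the least-squares optimal *proper* rotation (no
reflections) superposing one coordinate set on another; RMSD is reported
after applying it.  Trajectory RMSD fits every frame onto a reference frame
over a selected atom subset; RMSF measures each atom's fluctuation about its
trajectory-mean position after all frames are fitted to the first, averaged
per residue.

Trajectories are multi-model PDB (MODEL/ENDMDL); every model must have the
same atoms in the same order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, _parse_atom_line

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass(frozen=True)
class AtomMeta:
    name: str
    resname: str
    chain: str
    resseq: int
    element: str
    is_hetatm: bool = False

    @property
    def residue_label(self) -> str:
        return self.resname.capitalize() + str(self.resseq)


@dataclass
class Trajectory:
    """Frames (F x N x 3, angstrom) over a fixed atom list."""

    frames: np.ndarray
    atom_meta: list[AtomMeta]
    frame_times: np.ndarray | None = None  # ns, optional

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atom_meta):
            raise ValueError("atom_meta length does not match frame atom count")
        if self.frames.shape[0] < 1 or self.frames.shape[1] < 1:
            raise ValueError("trajectory needs at least one frame and one atom")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def read_trajectory(pdb_text: str) -> Trajectory:
    """Read a multi-model PDB into a Trajectory.

    A file without MODEL records is a single-frame trajectory.  All models
    must agree in atom count and order (checked by atom name/residue).
    """
    frames: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    saw_model = False
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith("MODEL"):
            saw_model = True
            current = []
        elif line.startswith("ENDMDL"):
            frames.append(current)
            current = []
        elif line.startswith(("ATOM", "HETATM")):
            atom = _parse_atom_line(line, lineno)
            if atom.altloc in ("", "A"):
                current.append(atom)
    if current:
        frames.append(current)
    frames = [f for f in frames if f]
    if not frames:
        raise ValueError("no coordinate frames found")
    meta = [
        AtomMeta(a.name, a.resname, a.chain, a.resseq, a.element, a.is_hetatm)
        for a in frames[0]
    ]
    key0 = [(m.name, m.resname, m.chain, m.resseq) for m in meta]
    coords = np.empty((len(frames), len(meta), 3))
    for fi, f in enumerate(frames):
        key = [(a.name, a.resname, a.chain, a.resseq) for a in f]
        if key != key0:
            raise ValueError(f"model {fi + 1} does not match the atom list of model 1")
        coords[fi] = [a.xyz for a in f]
    return Trajectory(frames=coords, atom_meta=meta)


def rmsd_plain(a: np.ndarray, b: np.ndarray) -> float:
    """No-fit RMSD between two pre-aligned N x 3 coordinate sets."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def superpose_kabsch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ m + translation`` best matches the reference in the
    (weighted) least-squares sense.  Reflections are forbidden: when the
    correlation matrix has negative determinant the smallest singular
    direction is sign-flipped, keeping det(R) = +1.

    Requires matching shapes with at least 3 non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"coordinate shapes differ: {mobile.shape} vs {reference.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * reference).sum(axis=0)
    m0 = mobile - mc
    r0 = reference - rc
    h = (w[:, None] * m0).T @ r0
    u, s, vt = np.linalg.svd(h)
    d = 1.0 if np.linalg.det(vt.T @ u.T) >= 0 else -1.0
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = rc - rot @ mc
    moved = m0 @ rot.T
    rmsd = float(np.sqrt((w * np.sum((moved - r0) ** 2, axis=1)).sum()))
    return rot, t, rmsd


SelectionSpec = str | Callable[[AtomMeta], bool]


def selection_mask(traj: Trajectory, selection: SelectionSpec = "ca") -> np.ndarray:
    """Boolean atom mask for a named or callable selection.

    Named selections: ``"ca"`` (Calpha of amino acids), ``"heavy"``
    (non-hydrogen), ``"ligand-heavy"`` (HETATM non-hydrogen), ``"all"``.
    """
    if callable(selection):
        pred = selection
    elif selection == "ca":
        pred = lambda m: m.name == "CA" and m.resname in AMINO_ACIDS
    elif selection == "heavy":
        pred = lambda m: m.element != "H"
    elif selection == "ligand-heavy":
        pred = lambda m: m.is_hetatm and m.element != "H"
    elif selection == "all":
        pred = lambda m: True
    else:
        raise ValueError(f"unknown selection {selection!r}")
    mask = np.array([bool(pred(m)) for m in traj.atom_meta])
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    return mask


def trajectory_rmsd(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: SelectionSpec = "ca",
) -> np.ndarray:
    """Per-frame Kabsch-fitted RMSD of the selected atoms vs a reference frame."""
    mask = selection_mask(traj, selection)
    ref = traj.frames[reference_frame][mask]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, _, out[i] = superpose_kabsch(traj.frames[i][mask], ref)
    return out


def trajectory_rmsf(
    traj: Trajectory, selection: SelectionSpec = "ca"
) -> dict[str, float]:
    """Per-residue RMSF (A) of the selected atoms.

    All frames are first fitted (Kabsch) onto the first frame over the
    selection; each atom's RMSF is the root-mean-square distance from its
    mean position, and residues average over their selected atoms.  Needs at
    least two frames.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    mask = selection_mask(traj, selection)
    sel_idx = np.flatnonzero(mask)
    ref = traj.frames[0][mask]
    fitted = np.empty((traj.n_frames, mask.sum(), 3))
    for i in range(traj.n_frames):
        rot, t, _ = superpose_kabsch(traj.frames[i][mask], ref)
        fitted[i] = traj.frames[i][mask] @ rot.T + t
    mean = fitted.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    acc: dict[str, list[float]] = {}
    for k, ai in enumerate(sel_idx):
        acc.setdefault(traj.atom_meta[ai].residue_label, []).append(per_atom[k])
    return {label: float(np.mean(vals)) for label, vals in acc.items()}


def stability_summary(
    traj_set: Mapping[str, Trajectory],
    selection: SelectionSpec = "ca",
    skip: int = 0,
    stable_rmsf_max: float = 0.6,
) -> pd.DataFrame:
    """Per-complex RMSD range and stable residues.

    ``skip`` discards the first frames (equilibration) before taking the
    (min, max) of the RMSD series; residues with RMSF at most
    ``stable_rmsf_max`` A are flagged stable.
    """
    if not traj_set:
        raise ValueError("empty trajectory set")
    rows = []
    for cid, traj in traj_set.items():
        series = trajectory_rmsd(traj, selection=selection)[skip:]
        if series.size == 0:
            raise ValueError(f"{cid}: equilibration skip leaves no frames")
        rmsf = trajectory_rmsf(traj, selection=selection)
        stable = [lab for lab, v in rmsf.items() if v <= stable_rmsf_max]
        rows.append(
            {
                "complex_id": cid,
                "rmsd_min": float(series.min()),
                "rmsd_max": float(series.max()),
                "n_frames": traj.n_frames,
                "stable_residues": ";".join(stable),
            }
        )
    return pd.DataFrame(rows)
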