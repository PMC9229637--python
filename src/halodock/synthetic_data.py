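"""Synthetic inputs with planted, known ground truth for every pipeline stage.

These generators stand in for quantum-chemistry, docking and MD outputs.  They
emulate the *statistical and geometric structure* the analysis assumes — a
halogen series whose LUMO drops with halogen rank and substitution count, a
binding pocket with noncovalent contacts planted at exact distances, a
trajectory with per-residue fluctuation amplitudes, a descriptor/score table
with a planted correlation — not the underlying physics.  Each generator is
fully deterministic per (config, seed) and returns its ground truth alongside
the artifact so tests never re-derive it.

Pocket fixtures reuse familiar active-site residue labels (Val143, Tyr155,
Pro187, Val188, His221, ...) so reports can be eyeballed against the style of
published interaction tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import OrbitalEnergies
from .structure_io import AtomRecord, ComplexStructure, format_pdb_atom
from .trajectory_metrics import AtomMeta, Trajectory

HALOGEN_RANK = {"F": 1, "Cl": 2, "Br": 3, "I": 4}

#: Reference-compound frontier orbitals (eV): hardness 2.12 eV, the value
#: typical of the unsubstituted hydroxyphenyl-naphthol parent scaffold.
REFERENCE_HOMO_EV = -5.74
REFERENCE_LUMO_EV = -1.50

#: Default per-step LUMO lowering (eV): one iodine substitution (rank 4)
#: then lowers the LUMO by 1.16 eV, giving a 3.08 eV gap for the mono-iodo
#: compound.
DEFAULT_LUMO_STEP = 0.29

#: Substitution patterns: R1/R2/R3 are single substitutions, R4 carries a
#: halogen at all three positions.
SUBSTITUTION_PATTERNS = (("R1", 1), ("R2", 1), ("R3", 1), ("R4", 3))


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_compounds: int = 100
    halogen_series: tuple[str, ...] = ("F", "Cl", "Br", "I")
    lumo_lowering_per_step: float = DEFAULT_LUMO_STEP
    orbital_jitter: float = 0.05  # uniform +- jitter on orbital energies (eV)
    planted_contacts: dict[str, list[float]] = field(default_factory=dict)
    decoys: bool = True
    traj_frames: int = 200
    n_residues: int = 80
    first_resseq: int = 130
    sigma_stable: float = 0.25  # A, fluctuation in the binding-residue regions
    sigma_loop: float = 0.80  # A, elsewhere
    stable_regions: tuple[tuple[int, int], ...] = ((140, 160), (180, 200))
    rigid_drift: bool = False
    planted_r: float = 0.8


# ---------------------------------------------------------------------------
# orbital tables


def gen_orbital_table(
    config: GeneratorConfig,
) -> tuple[list[OrbitalEnergies], dict]:
    """Reference compound plus a halogen series of frontier orbitals.

    HOMO is approximately constant; LUMO is lowered by
    ``lumo_lowering_per_step * rank(halogen) * n_substitutions`` plus a small
    uniform jitter, so the HOMO-LUMO gap (and hardness) strictly decreases
    along F -> Cl -> Br -> I within each substitution pattern.
    """
    rng = np.random.default_rng(config.seed)
    step = config.lumo_lowering_per_step
    jit = config.orbital_jitter

    def jitter() -> float:
        return float(rng.uniform(-jit, jit))

    out = [OrbitalEnergies("R", REFERENCE_HOMO_EV + jitter(), REFERENCE_LUMO_EV + jitter())]
    truth_rows = []
    for hal in config.halogen_series:
        rank = HALOGEN_RANK[hal]
        for pattern, nsub in SUBSTITUTION_PATTERNS:
            lowering = step * rank * nsub
            o = OrbitalEnergies(
                f"{hal}{pattern}",
                REFERENCE_HOMO_EV + jitter(),
                REFERENCE_LUMO_EV - lowering + jitter(),
            )
            out.append(o)
            truth_rows.append(
                {"compound_id": o.compound_id, "halogen": hal,
                 "n_substitutions": nsub, "lumo_lowering": lowering}
            )
    truth = {
        "reference": {"homo_ev": REFERENCE_HOMO_EV, "lumo_ev": REFERENCE_LUMO_EV},
        "lumo_lowering_per_step": step,
        "compounds": truth_rows,
    }
    return out, truth


# ---------------------------------------------------------------------------
# pocket complexes with planted contacts

_RING_R = 1.39
_HAL_BOND = 1.80
_O_BOND = 1.36
_CH_BOND = 1.09
_OH_BOND = 0.97

# azimuth (deg) of ligand substituent sites
_HAL_AZIMUTHS = (0.0, 60.0, 120.0)
_O_AZIMUTH = 240.0

# slot geometry: (azimuth index or fixed azimuth, elevation deg)
_HAL_SLOTS = tuple((site, elev) for elev in (0.0, 28.0) for site in (0, 1, 2))
_HB_SLOTS = (0.0, 40.0)  # elevations at the O azimuth
_PIPI_SLOTS = (1.0, -1.0)  # above / below the ring plane
_PIALKYL_SLOTS = (45.0, -45.0)  # elevation at azimuth 300

_HAL_RESIDUES = (("VAL", 143), ("VAL", 188), ("VAL", 225), ("MET", 147),
                 ("LEU", 149), ("ILE", 144), ("VAL", 145), ("LEU", 146))
_HB_RESIDUES = (("SER", 186), ("SER", 221))
_PIPI_RESIDUES = (("PHE", 226), ("TYR", 155))
_PIALKYL_RESIDUES = (("PRO", 187), ("ALA", 150))
_DECOY_BASE_RESSEQ = 300

#: Safe plant-distance ranges (A) per contact kind, inside each criterion.
PLANT_RANGES = {
    "halogen": (2.4, 3.9),
    "hbond": (2.65, 3.4),
    "pi_pi": (3.4, 5.3),
    "pi_alkyl": (3.5, 5.3),
}

_MAX_PLANTS = {"halogen": 6, "hbond": 2, "pi_pi": 2, "pi_alkyl": 2}


def _unit(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    az = math.radians(azimuth_deg)
    el = math.radians(elevation_deg)
    return np.array(
        [math.cos(az) * math.cos(el), math.sin(az) * math.cos(el), math.sin(el)]
    )


def _hexagon(center: np.ndarray, radius: float = _RING_R, z_normal: bool = True) -> list[np.ndarray]:
    pts = []
    for k in range(6):
        a = math.radians(60.0 * k)
        pts.append(center + radius * np.array([math.cos(a), math.sin(a), 0.0]))
    return pts


def gen_complex(
    config: GeneratorConfig,
    include_halogens: bool | None = None,
) -> tuple[ComplexStructure, dict]:
    """Build a minimal pocket/ligand complex realizing the requested plants.

    The ligand is a benzene-like six-ring (heavy atoms only) with up to three
    halogen substituents and one hydroxyl-style oxygen; receptor fragments
    (with explicit hydrogens where the contact requires them) are placed so
    that every entry of ``config.planted_contacts`` is realized at its exact
    target distance.  Decoy atoms just outside each criterion are added when
    ``config.decoys`` is set.  Returns the complex and a ground-truth dict
    with the planted counts and distances.  Raises ``ValueError`` for plants
    that cannot be realized (too many of one kind, out-of-range distance, or
    colliding geometry).
    """
    rng = np.random.default_rng(config.seed)
    plants = {k: sorted(v) for k, v in config.planted_contacts.items()}
    for kind, dists in plants.items():
        if kind not in _MAX_PLANTS:
            raise ValueError(f"unknown contact kind {kind!r}")
        if len(dists) > _MAX_PLANTS[kind]:
            raise ValueError(
                f"cannot plant {len(dists)} {kind} contacts "
                f"(at most {_MAX_PLANTS[kind]} supported)"
            )
        lo, hi = PLANT_RANGES[kind]
        for d in dists:
            if not (lo <= d <= hi):
                raise ValueError(
                    f"{kind} plant distance {d} outside realizable range [{lo}, {hi}]"
                )
    if include_halogens is None:
        include_halogens = bool(config.halogen_series)
    if plants.get("halogen") and not include_halogens:
        raise ValueError("halogen plants need a halogenated ligand")

    ligand: list[AtomRecord] = []
    receptor: list[AtomRecord] = []
    covalent: list[tuple[int, int]] = []  # indices into the merged atom list

    def lig(name, element, pos):
        ligand.append(
            AtomRecord(0, name, "LIG", "A", 1, tuple(np.round(pos, 3)), element, True)
        )

    def rec(name, element, pos, resname, resseq):
        receptor.append(
            AtomRecord(0, name, resname, "A", resseq, tuple(np.round(pos, 3)), element, False)
        )

    # --- ligand scaffold: hexagon in the z=0 plane
    origin = np.zeros(3)
    for i, p in enumerate(_hexagon(origin)):
        lig(f"C{i + 1}", "C", p)
    hal_positions: list[tuple[np.ndarray, np.ndarray]] = []  # (position, outward unit)
    if include_halogens:
        series = config.halogen_series or ("Cl",)
        for si, az in enumerate(_HAL_AZIMUTHS):
            u = _unit(az, 0.0)
            pos = origin + (_RING_R + _HAL_BOND) * u
            elem = series[int(rng.integers(len(series)))]
            lig(f"{elem.upper()}{si + 1}", elem, pos)
            hal_positions.append((pos, u))
    u_o = _unit(_O_AZIMUTH, 0.0)
    o_pos = origin + (_RING_R + _O_BOND) * u_o
    lig("O1", "O", o_pos)

    truth_dist: dict[str, list[float]] = {k: [] for k in _MAX_PLANTS}

    # --- halogen plants: receptor H (plus its carbon) along a slot direction
    for k, d in enumerate(plants.get("halogen", ())):
        site, elev = _HAL_SLOTS[k]
        if site >= len(hal_positions):
            raise ValueError("not enough halogen sites on the ligand")
        hal_pos, _ = hal_positions[site]
        az = _HAL_AZIMUTHS[site]
        u = _unit(az, elev)
        resname, resseq = _HAL_RESIDUES[k]
        rec("HB1", "H", hal_pos + d * u, resname, resseq)
        rec("CB", "C", hal_pos + (d + _CH_BOND) * u, resname, resseq)
        truth_dist["halogen"].append(d)

    # --- hydrogen-bond plants: Ser O-H donor aimed at the ligand oxygen
    for k, d in enumerate(plants.get("hbond", ())):
        elev = _HB_SLOTS[k]
        u = _unit(_O_AZIMUTH, elev)
        resname, resseq = _HB_RESIDUES[k]
        rec("OG", "O", o_pos + d * u, resname, resseq)
        rec("HG", "H", o_pos + (d - _OH_BOND) * u, resname, resseq)
        rec("CB", "C", o_pos + (d + 1.43) * u, resname, resseq)
        truth_dist["hbond"].append(d)

    # --- pi-pi plants: parallel aromatic six-ring above/below the ligand ring
    ring_names = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
    for k, d in enumerate(plants.get("pi_pi", ())):
        sign = _PIPI_SLOTS[k]
        center = origin + np.array([0.0, 0.0, sign * d])
        resname, resseq = _PIPI_RESIDUES[k]
        for name, p in zip(ring_names, _hexagon(center)):
            rec(name, "C", p, resname, resseq)
        truth_dist["pi_pi"].append(d)

    # --- pi-alkyl plants: aliphatic side-chain carbon near the ring centroid
    for k, d in enumerate(plants.get("pi_alkyl", ())):
        elev = _PIALKYL_SLOTS[k]
        u = _unit(300.0, elev)
        resname, resseq = _PIALKYL_RESIDUES[k]
        rec("CB", "C", origin + d * u, resname, resseq)
        truth_dist["pi_alkyl"].append(d)

    # --- decoys just outside each criterion
    if config.decoys:
        seq = _DECOY_BASE_RESSEQ
        if hal_positions:
            hal_pos, _ = hal_positions[0]
            u = _unit(_HAL_AZIMUTHS[0], -30.0)
            d = float(rng.uniform(4.4, 5.5))
            rec("HD1", "H", hal_pos + d * u, "LEU", seq)
            rec("CD1", "C", hal_pos + (d + _CH_BOND) * u, "LEU", seq)
            seq += 1
        u = _unit(_O_AZIMUTH, -40.0)
        rec("OD1", "O", o_pos + float(rng.uniform(4.2, 5.0)) * u, "ASN", seq)
        seq += 1
        center = origin + float(rng.uniform(6.2, 7.0)) * _unit(180.0, 20.0)
        for name, p in zip(ring_names, _hexagon(center)):
            rec(name, "C", p, "PHE", seq)
        seq += 1
        rec("CD1", "C", origin + float(rng.uniform(5.9, 6.5)) * _unit(300.0, 0.0), "LEU", seq)

    # renumber serials over receptor then ligand
    receptor = [
        AtomRecord(i + 1, a.name, a.resname, a.chain, a.resseq, a.xyz, a.element, False)
        for i, a in enumerate(receptor)
    ]
    off = len(receptor)
    ligand = [
        AtomRecord(off + i + 1, a.name, a.resname, a.chain, a.resseq, a.xyz, a.element, True)
        for i, a in enumerate(ligand)
    ]

    _check_no_collisions(receptor + ligand)

    cplx = ComplexStructure(receptor=receptor, ligand=ligand)
    cplx.annotate_ligand()
    truth = {
        "counts": {k: len(v) for k, v in truth_dist.items()},
        "distances": truth_dist,
        "ligand_halogens": sum(1 for a in ligand if a.element in {"F", "Cl", "Br", "I"}),
    }
    return cplx, truth


def _check_no_collisions(atoms: Sequence[AtomRecord], min_dist: float = 0.8) -> None:
    """Reject geometries with non-bonded atoms closer than ``min_dist`` A."""
    coords = np.array([a.coords for a in atoms])
    n = len(atoms)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            same_res = (
                atoms[i].resseq == atoms[j].resseq
                and atoms[i].is_hetatm == atoms[j].is_hetatm
            )
            if d < min_dist and not same_res:
                raise ValueError(
                    f"unsatisfiable plant geometry: {atoms[i].name}/{atoms[i].residue_label} "
                    f"and {atoms[j].name}/{atoms[j].residue_label} overlap at {d:.2f} A"
                )


def random_plants(rng: np.random.Generator) -> dict[str, list[float]]:
    """Draw a random valid plant specification (counts and distances)."""
    plants: dict[str, list[float]] = {}
    maxima = {"halogen": 5, "hbond": 2, "pi_pi": 2, "pi_alkyl": 2}
    for kind, mx in maxima.items():
        n = int(rng.integers(0, mx + 1))
        lo, hi = PLANT_RANGES[kind]
        plants[kind] = sorted(float(rng.uniform(lo, hi)) for _ in range(n))
    return plants


# ---------------------------------------------------------------------------
# trajectories


def _sigma_for(resseq: int, config: GeneratorConfig) -> float:
    for lo, hi in config.stable_regions:
        if lo <= resseq <= hi:
            return config.sigma_stable
    return config.sigma_loop


def gen_trajectory(
    config: GeneratorConfig,
    sigma_override: float | Mapping[int, float] | None = None,
) -> tuple[Trajectory, dict]:
    """Calpha trajectory: a fixed backbone plus per-residue Gaussian jitter.

    The base structure is a gentle helix of ``n_residues`` Calpha atoms.
    Each frame displaces every atom by isotropic Gaussian noise whose
    per-residue sigma comes from the stable/loop profile (low sigma inside
    ``stable_regions``), or from ``sigma_override`` (a scalar, or a
    resseq -> sigma map).  With ``rigid_drift`` each frame additionally gets
    a rigid rotation + translation, which superposition must remove.
    """
    if config.traj_frames < 1:
        raise ValueError("traj_frames must be >= 1")
    rng = np.random.default_rng(config.seed)
    n = config.n_residues
    resseqs = list(range(config.first_resseq, config.first_resseq + n))
    if sigma_override is None:
        sigmas = np.array([_sigma_for(r, config) for r in resseqs])
    elif isinstance(sigma_override, Mapping):
        sigmas = np.array([float(sigma_override.get(r, config.sigma_loop)) for r in resseqs])
    else:
        sigmas = np.full(n, float(sigma_override))

    t = np.arange(n)
    base = np.stack(
        [10.0 * np.cos(t * 0.35), 10.0 * np.sin(t * 0.35), 1.5 * t], axis=1
    )
    frames = np.empty((config.traj_frames, n, 3))
    for f in range(config.traj_frames):
        noise = rng.normal(0.0, 1.0, size=(n, 3)) * sigmas[:, None]
        frame = base + noise
        if config.rigid_drift:
            ang = 0.01 * f
            c, s = math.cos(ang), math.sin(ang)
            rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
            frame = frame @ rot.T + np.array([0.05 * f, -0.02 * f, 0.01 * f])
        frames[f] = frame
    meta = [AtomMeta("CA", "ALA", "A", r, "C") for r in resseqs]
    traj = Trajectory(frames=frames, atom_meta=meta)
    truth = {
        "sigma_per_residue": {str(r): float(s) for r, s in zip(resseqs, sigmas)},
        "rigid_drift": config.rigid_drift,
        "stable_regions": [list(x) for x in config.stable_regions],
    }
    return traj, truth


def trajectory_to_pdb(traj: Trajectory) -> str:
    """Serialize a trajectory as a multi-model PDB."""
    lines: list[str] = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:>4}")
        for i, m in enumerate(traj.atom_meta):
            atom = AtomRecord(
                i + 1, m.name, m.resname, m.chain, m.resseq,
                tuple(np.round(traj.frames[f, i], 3)), m.element, m.is_hetatm,
            )
            lines.append(format_pdb_atom(atom))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# descriptor/score tables with a planted correlation


def gen_property_table(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Descriptor/score table with corr(mu, binding_energy) = ``planted_r``.

    (mu, binding_energy) pairs are drawn from a bivariate normal centered at
    realistic values (mu -4 eV, dG -11 kcal/mol); hardness is drawn
    independently and the remaining descriptor columns follow from the exact
    finite-difference identities (omega = mu^2/2eta, S = 1/2eta, gap = 2eta).
    """
    r = config.planted_r
    if not -1.0 < r < 1.0:
        raise ValueError(f"planted_r must lie in (-1, 1), got {r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_compounds
    z1 = rng.normal(size=n)
    z2 = rng.normal(size=n)
    mu = -4.0 + 0.4 * z1
    dg = -11.0 + 0.5 * (r * z1 + math.sqrt(1.0 - r * r) * z2)
    eta = rng.uniform(1.5, 2.2, size=n)
    table = pd.DataFrame(
        {
            "compound_id": [f"S{i:04d}" for i in range(n)],
            "mu": mu,
            "omega": mu**2 / (2.0 * eta),
            "eta": eta,
            "softness": 1.0 / (2.0 * eta),
            "gap": 2.0 * eta,
            "binding_energy": dg,
        }
    )
    truth = {"planted_r": r, "n": n, "correlated_column": "mu"}
    return table, truth


# ---------------------------------------------------------------------------
# docking records with the halogen-series energy trend


def gen_docking_records(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Docking energies emulating the F < Cl < Br < I binding trend.

    Mean dG deepens by 0.45 kcal/mol per halogen rank from a -10.4 kcal/mol
    fluorine baseline, with +-0.1 kcal/mol within-class jitter (small enough
    that class means stay strictly ordered for every seed).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for hal in config.halogen_series:
        rank = HALOGEN_RANK[hal]
        for pattern, nsub in SUBSTITUTION_PATTERNS:
            dg = -10.4 - 0.45 * (rank - 1) - 0.05 * nsub + float(rng.uniform(-0.1, 0.1))
            rows.append(
                {
                    "compound_id": f"{hal}{pattern}",
                    "binding_energy": round(dg, 3),
                    "halogen": hal,
                    "n_substitutions": nsub,
                }
            )
    truth = {"trend": "F < Cl < Br < I", "per_rank_deepening": 0.45}
    return pd.DataFrame(rows), truth


def write_truth_sidecar(path, truth: dict) -> None:
    """Write a generator's ground truth next to its artifact."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
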