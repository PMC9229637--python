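"""Shared fixtures and independent brute-force oracles for detector checks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from halodock.structure_io import ComplexStructure, HALOGEN_ELEMENTS


def brute_force_halogen(cplx: ComplexStructure, cutoff: float = 4.0) -> int:
    """Independent all-pairs count of receptor-H / ligand-halogen contacts."""
    n = 0
    for h in cplx.receptor:
        if h.element != "H":
            continue
        for x in cplx.ligand:
            if x.element in HALOGEN_ELEMENTS:
                if math.dist(h.xyz, x.xyz) < cutoff:
                    n += 1
    return n


def brute_force_hbond(cplx: ComplexStructure, d_max: float = 3.5, angle_min: float = 120.0) -> int:
    """All-pairs N/O/S pair count with explicit-H angle screening."""
    polar = {"N", "O", "S"}

    def hyds(atoms, heavy):
        return [a for a in atoms if a.element == "H" and math.dist(a.xyz, heavy.xyz) <= 1.2]

    def ang(p, v, q):
        u = np.array(p) - np.array(v)
        w = np.array(q) - np.array(v)
        c = u @ w / (np.linalg.norm(u) * np.linalg.norm(w))
        return math.degrees(math.acos(max(-1, min(1, c))))

    n = 0
    for r in cplx.receptor:
        if r.element not in polar:
            continue
        for l in cplx.ligand:
            if l.element not in polar:
                continue
            if math.dist(r.xyz, l.xyz) > d_max:
                continue
            hs = hyds(cplx.receptor, r) + hyds(cplx.ligand, l)
            if hs:
                best = max(
                    ang(r.xyz, h.xyz, l.xyz) if math.dist(h.xyz, r.xyz) <= 1.2
                    else ang(l.xyz, h.xyz, r.xyz)
                    for h in hs
                )
                if best < angle_min:
                    continue
            n += 1
    return n


def rigid_transform(rng: np.random.Generator):
    """A random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-20, 20, size=3)
    return rot, t


def transform_complex(cplx: ComplexStructure, rot: np.ndarray, t: np.ndarray) -> ComplexStructure:
    from dataclasses import replace

    def move(atoms):
        return [
            replace(a, xyz=tuple(np.round(rot @ np.asarray(a.xyz) + t, 6)))
            for a in atoms
        ]

    moved = ComplexStructure(receptor=move(cplx.receptor), ligand=move(cplx.ligand))
    moved.annotate_ligand()
    return moved


@pytest.fixture
def planted_complex():
    from halodock.synthetic_data import GeneratorConfig, gen_complex

    cfg = GeneratorConfig(
        seed=42,
        planted_contacts={"halogen": [3.2, 3.8], "hbond": [2.9], "pi_pi": [3.8], "pi_alkyl": [4.0]},
    )
    return gen_complex(cfg)
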