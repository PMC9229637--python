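"""Kabsch superposition, plain RMSD, trajectory RMSD/RMSF and summaries."""

import math

import numpy as np
import pytest

from conftest import rigid_transform
from halodock.synthetic_data import GeneratorConfig, gen_trajectory, trajectory_to_pdb
from halodock.trajectory_metrics import (
    AtomMeta,
    Trajectory,
    read_trajectory,
    rmsd_plain,
    stability_summary,
    superpose_kabsch,
    trajectory_rmsd,
    trajectory_rmsf,
)


def _cloud(rng, n=12):
    return rng.normal(scale=3.0, size=(n, 3))


class TestKabsch:
    def test_identity(self):
        pts = _cloud(np.random.default_rng(0))
        _, _, r = superpose_kabsch(pts, pts)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_removed(self):
        pts = _cloud(np.random.default_rng(1))
        rot90 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ rot90.T + np.array([5.0, 0.0, 0.0])
        _, _, r = superpose_kabsch(moved, pts)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_grid_search_oracle(self):
        """Optimal RMSD agrees with a brute-force scan over rotation angles."""
        mobile = np.array([[0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.3, 0.4, 1.2]])
        reference = np.array([[0.1, 0, 0], [1.4, 0.2, 0], [-0.1, 1.9, 0.3], [0.5, 0.2, 1.0]])
        _, _, fitted = superpose_kabsch(mobile, reference)

        def rot_zyx(a, b, c):
            ca, sa, cb, sb, cc, sc = map(float, (np.cos(a), np.sin(a), np.cos(b), np.sin(b), np.cos(c), np.sin(c)))
            rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
            rx = np.array([[1, 0, 0], [0, cc, -sc], [0, sc, cc]])
            return rz @ ry @ rx

        m0 = mobile - mobile.mean(axis=0)
        r0 = reference - reference.mean(axis=0)

        def objective(angles):
            return rmsd_plain(m0 @ rot_zyx(*angles).T, r0)

        best, best_angles = np.inf, None
        grid = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        half = np.linspace(-np.pi / 2, np.pi / 2, 21)
        for a in grid:
            for b in half:
                for c in grid:
                    v = objective((a, b, c))
                    if v < best:
                        best, best_angles = v, (a, b, c)
        from scipy.optimize import minimize

        refined = minimize(objective, best_angles, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12}).fun
        assert fitted <= refined + 1e-9
        assert fitted == pytest.approx(refined, abs=1e-6)

    def test_rotation_is_proper_orthogonal(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a, b = _cloud(rng), _cloud(rng)
            rot, _, _ = superpose_kabsch(a, b)
            assert np.allclose(rot @ rot.T, np.eye(3), atol=1e-10)
            assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)

    def test_never_exceeds_plain_rmsd_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a, b = _cloud(rng), _cloud(rng)
            _, _, fitted = superpose_kabsch(a, b)
            _, _, flipped = superpose_kabsch(b, a)
            assert fitted <= rmsd_plain(a, b) + 1e-12
            assert fitted == pytest.approx(flipped, abs=1e-9)

    def test_invariant_to_rigid_premotion(self):
        rng = np.random.default_rng(11)
        a, b = _cloud(rng), _cloud(rng)
        _, _, base = superpose_kabsch(a, b)
        rot, t = rigid_transform(rng)
        _, _, moved = superpose_kabsch(a @ rot.T + t, b)
        assert moved == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("n", [1, 2])
    def test_too_few_points_rejected(self, n):
        pts = np.zeros((n, 3))
        with pytest.raises(ValueError):
            superpose_kabsch(pts, pts)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            superpose_kabsch(np.zeros((4, 3)), np.zeros((5, 3)))


class TestPlainRmsd:
    def test_identical_zero(self):
        a = np.arange(12.0).reshape(4, 3)
        assert rmsd_plain(a, a) == 0.0

    def test_uniform_unit_shift(self):
        a = np.zeros((5, 3))
        b = a + np.array([1.0, 0, 0])
        assert rmsd_plain(a, b) == pytest.approx(1.0)

    def test_hand_arithmetic_two_atoms(self):
        a = np.zeros((2, 3))
        b = np.array([[3.0, 0, 0], [0, 4.0, 0]])
        assert rmsd_plain(a, b) == pytest.approx(math.sqrt((9 + 16) / 2))


def _static_traj(n_frames=5, n_atoms=8):
    rng = np.random.default_rng(0)
    base = rng.normal(scale=4.0, size=(n_atoms, 3))
    frames = np.repeat(base[None], n_frames, axis=0)
    meta = [AtomMeta("CA", "ALA", "A", 100 + i, "C") for i in range(n_atoms)]
    return Trajectory(frames=frames, atom_meta=meta)


class TestTrajectoryMetrics:
    def test_static_trajectory_all_zero_rmsd(self):
        assert np.allclose(trajectory_rmsd(_static_traj()), 0.0, atol=1e-12)

    def test_rigidly_rotated_frames_zero_rmsd(self):
        traj, _ = gen_trajectory(
            GeneratorConfig(seed=2, traj_frames=15, n_residues=20, rigid_drift=True),
            sigma_override=0.0,
        )
        assert np.allclose(trajectory_rmsd(traj), 0.0, atol=1e-9)

    def test_reference_frame_entry_is_zero(self):
        traj, _ = gen_trajectory(GeneratorConfig(seed=4, traj_frames=10, n_residues=15))
        series = trajectory_rmsd(traj, reference_frame=3)
        assert series[3] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_jitter_rmsd_matches_direct_evaluation(self):
        """Kabsch-series equals an independently coded per-frame evaluation."""
        traj, _ = gen_trajectory(
            GeneratorConfig(seed=6, traj_frames=50, n_residues=25), sigma_override=0.5
        )
        series = trajectory_rmsd(traj)
        ref = traj.frames[0]
        for i in (0, 10, 49):
            _, _, direct = superpose_kabsch(traj.frames[i], ref)
            assert series[i] == pytest.approx(direct, abs=1e-12)
        # mean close to the sigma*sqrt(3) displacement scale (x2 for both frames noisy)
        assert 0.5 < series[1:].mean() < 2.0

    def test_empty_selection_rejected(self):
        traj = _static_traj()
        with pytest.raises(ValueError, match="no atoms"):
            trajectory_rmsd(traj, selection="ligand-heavy")

    def test_static_rmsf_zero(self):
        rmsf = trajectory_rmsf(_static_traj())
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in rmsf.values())

    def test_single_frame_rmsf_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            trajectory_rmsf(_static_traj(n_frames=1))

    def test_two_point_alternation_rmsf_equals_amplitude(self):
        """Atoms alternating +-d about their means have RMSF exactly d.

        The displacement pattern is translation- and torque-free (two atoms
        on the x axis moving oppositely along x), so the superposition fit is
        the identity and the two-point variance closed form applies exactly.
        """
        d = 0.7
        base = np.array(
            [[3.0, 0, 0], [-3.0, 0, 0], [0, 2.5, 0], [0, -2.5, 1.0],
             [1.0, 1.0, 3.0], [-1.0, 2.0, -2.0]]
        )
        f1, f2 = base.copy(), base.copy()
        f1[0, 0] += d
        f1[1, 0] -= d
        f2[0, 0] -= d
        f2[1, 0] += d
        meta = [AtomMeta("CA", "GLY", "A", 200 + i, "C") for i in range(6)]
        traj = Trajectory(frames=np.stack([f1, f2] * 10), atom_meta=meta)
        rmsf = trajectory_rmsf(traj)
        assert rmsf["Gly200"] == pytest.approx(d, abs=1e-9)
        assert rmsf["Gly201"] == pytest.approx(d, abs=1e-9)
        assert rmsf["Gly202"] == pytest.approx(0.0, abs=1e-9)

    def test_rmsf_invariant_under_global_rigid_motion(self):
        traj, _ = gen_trajectory(GeneratorConfig(seed=8, traj_frames=30, n_residues=20))
        base = trajectory_rmsf(traj)
        rot, t = rigid_transform(np.random.default_rng(5))
        moved = Trajectory(frames=traj.frames @ rot.T + t, atom_meta=traj.atom_meta)
        for k, v in trajectory_rmsf(moved).items():
            assert v == pytest.approx(base[k], abs=1e-9)

    def test_sigma_recovery_from_rmsf(self):
        """Isotropic jitter sigma is recovered as RMSF/sqrt(3) within 8%."""
        traj, _ = gen_trajectory(
            GeneratorConfig(seed=12, traj_frames=4000, n_residues=30), sigma_override=0.5
        )
        vals = np.array(list(trajectory_rmsf(traj).values()))
        assert (vals / math.sqrt(3)).mean() == pytest.approx(0.5, rel=0.08)


class TestStabilitySummary:
    def test_range_and_identical_rows(self):
        traj, _ = gen_trajectory(GeneratorConfig(seed=3, traj_frames=30, n_residues=30))
        df = stability_summary({"a": traj, "b": traj})
        assert len(df) == 2
        a, b = df.iloc[0], df.iloc[1]
        assert a.rmsd_min <= a.rmsd_max
        assert (a.rmsd_min, a.rmsd_max, a.stable_residues) == (b.rmsd_min, b.rmsd_max, b.stable_residues)

    def test_low_sigma_regions_flagged_stable(self):
        cfg = GeneratorConfig(seed=9, traj_frames=80, n_residues=80, first_resseq=130)
        traj, truth = gen_trajectory(cfg)
        df = stability_summary({"x": traj}, stable_rmsf_max=0.6)
        stable = set(df.iloc[0].stable_residues.split(";"))
        stable_seqs = {int(s[3:]) for s in stable if s}
        expected = {r for r in range(130, 210) if 140 <= r <= 160 or 180 <= r <= 200}
        assert stable_seqs == expected

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            stability_summary({})


class TestTrajectoryIO:
    def test_multi_model_round_trip(self):
        traj, _ = gen_trajectory(GeneratorConfig(seed=1, traj_frames=4, n_residues=6))
        back = read_trajectory(trajectory_to_pdb(traj))
        assert back.n_frames == 4 and back.n_atoms == 6
        assert np.allclose(back.frames, np.round(traj.frames, 3), atol=1e-9)
        assert [m.residue_label for m in back.atom_meta] == [
            m.residue_label for m in traj.atom_meta
        ]

    def test_mismatched_models_rejected(self):
        text = (
            "MODEL     1\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL     2\n"
            "ATOM      1  CA  GLY A   2       0.000   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
        )
        with pytest.raises(ValueError, match="model 2"):
            read_trajectory(text)

    def test_no_frames_rejected(self):
        with pytest.raises(ValueError):
            read_trajectory("END\n")
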