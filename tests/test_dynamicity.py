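"""Trajectory superposition, convex-hull explored volumes, apo/holo ratios."""

from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import sensilla as sl
from sensilla.dynamicity import (Trajectory, atom_explored_volume,
                                 concatenate_replicas, dynamicity_profile,
                                 kabsch, mean_relative_dynamicity,
                                 read_trajectory, relative_dynamicity, rmsd,
                                 superpose_frames, validate_unwrapped,
                                 write_trajectory)


def hull_volume_oracle(points: np.ndarray) -> float:
    """Independent convex-hull volume: exhaustive facet search + tetrahedra.

    Every triple of points whose plane has all remaining points strictly on
    one side is a hull facet; the volume is the sum of tetrahedra formed by
    each facet with an interior point (the centroid).  Valid for points in
    general position (no 4 coplanar hull points).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    idx = np.array(list(combinations(range(n), 3)))
    a, b, c = pts[idx[:, 0]], pts[idx[:, 1]], pts[idx[:, 2]]
    normals = np.cross(b - a, c - a)
    offsets = np.einsum("mk,mk->m", normals, a)
    d = pts @ normals.T - offsets[None, :]          # (n_points, n_triples)
    scale = np.abs(d).max(axis=0) + 1e-300
    tol = 1e-10 * scale
    pos = (d >= -tol[None, :]).all(axis=0)
    neg = (d <= tol[None, :]).all(axis=0)
    facet = (pos | neg) & (np.linalg.norm(normals, axis=1) > 1e-12)
    centroid = pts.mean(axis=0)
    vols = np.abs(np.einsum("mk,mk->m", normals[facet],
                            centroid - a[facet])) / 6.0
    return float(vols.sum())


def random_rotation(seed: int) -> np.ndarray:
    return Rotation.random(1, rng=np.random.default_rng(seed)
                           ).as_matrix()[0]


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

class TestIO:
    def test_two_model_pdb_fixture(self, tmp_path):
        traj = Trajectory(np.random.default_rng(0).normal(size=(2, 6, 3)) * 5)
        path = tmp_path / "two.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 2
        assert back.n_atoms == 6

    def test_pdb_round_trip_to_printed_precision(self, tmp_path):
        cfg = sl.TrajectorySimConfig(n_atoms=20, n_frames=4, seed=1)
        traj, _ = sl.simulate_trajectory(cfg)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert np.abs(back.coords - traj.coords).max() < 1e-3 + 5e-4
        assert np.array_equal(back.residue_ids, traj.residue_ids)

    def test_xyz_round_trip(self, tmp_path):
        cfg = sl.TrajectorySimConfig(n_atoms=15, n_frames=3, seed=2)
        traj, _ = sl.simulate_trajectory(cfg)
        path = tmp_path / "traj.xyz"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert np.abs(back.coords - traj.coords).max() < 1e-5

    def test_atom_count_mismatch_names_model(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("2\nf1\nC 0 0 0\nC 1 0 0\n3\nf2\nC 0 0 0\nC 1 0 0\nC 2 0 0\n")
        with pytest.raises(ValueError, match="model 2"):
            read_trajectory(path)

    def test_truncated_model_is_parse_error(self, tmp_path):
        path = tmp_path / "trunc.xyz"
        path.write_text("3\nf1\nC 0 0 0\nC 1 0 0\n")
        with pytest.raises(ValueError):
            read_trajectory(path)


class TestConcatenate:
    def test_three_replicas_frame_count(self):
        replicas = []
        for seed in range(3):
            cfg = sl.TrajectorySimConfig(n_atoms=10, n_frames=100, seed=seed)
            replicas.append(sl.simulate_trajectory(cfg)[0])
        combined = concatenate_replicas(replicas)
        assert combined.n_frames == 300
        assert np.array_equal(np.unique(combined.replica_ids), [0, 1, 2])

    def test_split_recovers_originals(self):
        replicas = [sl.simulate_trajectory(
            sl.TrajectorySimConfig(n_atoms=8, n_frames=20, seed=s))[0]
            for s in range(2)]
        combined = concatenate_replicas(replicas)
        for i, original in enumerate(replicas):
            sub = combined.coords[combined.replica_ids == i]
            assert np.array_equal(sub, original.coords)

    def test_hull_volume_invariant_to_frame_order(self):
        cfg = sl.TrajectorySimConfig(n_atoms=5, n_frames=50, seed=3,
                                     rigid_rotation_jitter=0.0,
                                     rigid_translation_jitter=0.0)
        traj, _ = sl.simulate_trajectory(cfg)
        perm = np.random.default_rng(0).permutation(traj.n_frames)
        shuffled = Trajectory(traj.coords[perm],
                              residue_ids=traj.residue_ids)
        for atom in range(traj.n_atoms):
            v1, _ = atom_explored_volume(traj, atom)
            v2, _ = atom_explored_volume(shuffled, atom)
            assert v1 == pytest.approx(v2, rel=1e-12)

    def test_atom_map_mismatch_raises(self):
        t1 = Trajectory(np.zeros((2, 4, 3)), residue_ids=[1, 1, 2, 2])
        t2 = Trajectory(np.zeros((2, 4, 3)), residue_ids=[1, 2, 3, 4])
        with pytest.raises(ValueError):
            concatenate_replicas([t1, t2])


# --------------------------------------------------------------------------
# Superposition
# --------------------------------------------------------------------------

class TestSuperposition:
    def test_identical_frames_zero_rmsd(self):
        frame = np.random.default_rng(0).normal(size=(10, 3)) * 4
        traj = Trajectory(np.stack([frame] * 5))
        fitted = superpose_frames(traj)
        for f in range(5):
            assert rmsd(fitted.coords[f], frame) < 1e-12

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_recovery_of_applied_rotation(self, seed):
        rng = np.random.default_rng(seed)
        ref = rng.normal(size=(25, 3)) * 6
        rot_true = random_rotation(seed)
        shift = rng.normal(size=3) * 10
        moved = ref @ rot_true.T + shift
        rot, trans = kabsch(moved, ref)
        assert rmsd(moved @ rot.T + trans, ref) < 1e-9
        assert np.allclose(rot @ rot_true, np.eye(3), atol=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(7)
        mobile = rng.normal(size=(12, 3))
        ref = rng.normal(size=(12, 3))
        rot, trans = kabsch(mobile, ref)
        est, _ = Rotation.align_vectors(ref - ref.mean(0),
                                        mobile - mobile.mean(0))
        assert np.allclose(rot, est.as_matrix(), atol=1e-8)

    def test_optimality_vs_rotation_grid_on_toy_case(self):
        """Kabsch RMSD beats every rotation on a dense Euler-angle grid."""
        rng = np.random.default_rng(3)
        mobile = rng.normal(size=(4, 3)) * 3
        ref = rng.normal(size=(4, 3)) * 3
        rot, trans = kabsch(mobile, ref)
        best = rmsd(mobile @ rot.T + trans, ref)
        grid = np.linspace(0, 2 * np.pi, 20, endpoint=False)
        mc, rc = mobile.mean(0), ref.mean(0)
        for a in grid:
            for b in np.linspace(0, np.pi, 10):
                for c in grid:
                    r = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                    candidate = rmsd((mobile - mc) @ r.T + rc, ref)
                    assert best <= candidate + 1e-9

    def test_idempotent(self, loop_trajectory):
        traj, _, _ = loop_trajectory
        once = superpose_frames(traj)
        twice = superpose_frames(once)
        assert np.allclose(once.coords, twice.coords, atol=1e-9)

    def test_post_fit_rmsd_never_worse(self, loop_trajectory):
        traj, _, _ = loop_trajectory
        fitted = superpose_frames(traj)
        ref = traj.coords[0]
        for f in range(0, traj.n_frames, 50):
            assert (rmsd(fitted.coords[f], ref)
                    <= rmsd(traj.coords[f], ref) + 1e-12)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5, dtype=float), [1.0, 0.0, 0.0])
        traj = Trajectory(np.stack([line, line + 1.0]))
        with pytest.raises(ValueError):
            superpose_frames(traj)


# --------------------------------------------------------------------------
# Explored volumes
# --------------------------------------------------------------------------

class TestExploredVolume:
    def test_unit_cube_corners(self):
        corners = np.array([[x, y, z] for x in (0, 1) for y in (0, 1)
                            for z in (0, 1)], dtype=float)
        traj = Trajectory(corners[:, None, :])
        volume, degenerate = atom_explored_volume(traj, 0)
        assert volume == pytest.approx(1.0)
        assert not degenerate

    @pytest.mark.parametrize("n_frames", [1, 2, 3])
    def test_three_or_fewer_points_degenerate(self, n_frames):
        traj = Trajectory(np.random.default_rng(0).normal(
            size=(n_frames, 1, 3)))
        volume, degenerate = atom_explored_volume(traj, 0)
        assert volume == 0.0 and degenerate

    def test_coplanar_points_degenerate_zero(self):
        rng = np.random.default_rng(1)
        flat = rng.normal(size=(30, 3))
        flat[:, 2] = 0.0
        traj = Trajectory(flat[:, None, :])
        volume, degenerate = atom_explored_volume(traj, 0)
        assert volume == 0.0 and degenerate

    def test_200_random_ball_points_match_oracle(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(200, 3))
        points /= np.maximum(1.0, np.linalg.norm(points, axis=1,
                                                 keepdims=True))
        traj = Trajectory(points[:, None, :])
        volume, _ = atom_explored_volume(traj, 0)
        assert volume == pytest.approx(hull_volume_oracle(points), rel=1e-9)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        points = rng.normal(size=(40, 3))
        rot = random_rotation(2)
        moved = points @ rot.T + np.array([5.0, -3.0, 2.0])
        v1, _ = atom_explored_volume(Trajectory(points[:, None, :]), 0)
        v2, _ = atom_explored_volume(Trajectory(moved[:, None, :]), 0)
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_monotone_under_point_addition(self):
        rng = np.random.default_rng(8)
        points = rng.normal(size=(60, 3))
        volumes = []
        for n in (10, 20, 40, 60):
            v, _ = atom_explored_volume(Trajectory(points[:n, None, :]), 0)
            volumes.append(v)
        assert (np.diff(volumes) >= -1e-12).all()


class TestProfile:
    def test_doubled_frames_halve_per_step_volume(self):
        cfg = sl.TrajectorySimConfig(n_atoms=10, n_frames=50, seed=4,
                                     rigid_rotation_jitter=0.0,
                                     rigid_translation_jitter=0.0)
        traj, _ = sl.simulate_trajectory(cfg)
        doubled = Trajectory(np.concatenate([traj.coords, traj.coords]),
                             residue_ids=traj.residue_ids)
        p1 = dynamicity_profile(traj)
        p2 = dynamicity_profile(doubled)
        assert np.allclose(p2.explored_volume, p1.explored_volume)
        assert np.allclose(p2.per_step_volume, p1.per_step_volume / 2)

    def test_loop_residues_have_highest_per_residue_volume(self,
                                                           loop_trajectory):
        traj, _, cfg = loop_trajectory
        prof = dynamicity_profile(superpose_frames(traj))
        per_res = prof.per_residue()
        loop_res = set(np.asarray(traj.residue_ids)[
            list(cfg.loop_atom_indices)])
        top = per_res.nlargest(len(loop_res), "per_step_volume")
        assert set(top["residue_id"]) == loop_res

    def test_windowed_mode_averages_block_hulls(self):
        cfg = sl.TrajectorySimConfig(n_atoms=6, n_frames=40, seed=5,
                                     rigid_rotation_jitter=0.0,
                                     rigid_translation_jitter=0.0)
        traj, _ = sl.simulate_trajectory(cfg)
        prof = dynamicity_profile(traj, window=10)
        manual = np.mean([
            atom_explored_volume(Trajectory(traj.coords[b*10:(b+1)*10]), 0)[0]
            for b in range(4)])
        assert prof.explored_volume[0] == pytest.approx(manual)

    def test_unwrapped_validation_flags_jumps(self):
        coords = np.zeros((3, 2, 3))
        coords[1, 0, 0] = 50.0  # box-size jump
        with pytest.warns(UserWarning):
            assert not validate_unwrapped(Trajectory(coords))


class TestRelative:
    def test_holo_equals_apo_gives_unit_ratios(self, loop_trajectory):
        traj, _, _ = loop_trajectory
        prof = dynamicity_profile(superpose_frames(traj))
        ratios = relative_dynamicity(prof, prof)
        assert np.allclose(ratios.loc[~ratios["excluded"], "ratio"], 1.0)

    def test_global_stabilization_mean_ratio_below_one(self):
        apo_cfg = sl.TrajectorySimConfig(n_atoms=80, n_frames=300,
                                         base_sigma=0.5, loop_sigma=0.5,
                                         seed=21)
        holo_cfg = sl.TrajectorySimConfig(n_atoms=80, n_frames=300,
                                          base_sigma=0.4, loop_sigma=0.4,
                                          seed=22)
        apo = dynamicity_profile(superpose_frames(
            sl.simulate_trajectory(apo_cfg)[0]))
        holo = dynamicity_profile(superpose_frames(
            sl.simulate_trajectory(holo_cfg)[0]))
        ratios = relative_dynamicity(holo, apo)
        assert mean_relative_dynamicity(ratios) < 1.0

    def test_mobilized_loop_flagged_high(self):
        loop = tuple(range(60, 70))
        apo_cfg = sl.TrajectorySimConfig(n_atoms=80, n_frames=300,
                                         base_sigma=0.5, loop_sigma=0.5,
                                         seed=31)
        holo_cfg = sl.TrajectorySimConfig(n_atoms=80, n_frames=300,
                                          base_sigma=0.4,
                                          loop_atom_indices=loop,
                                          loop_sigma=1.0, seed=32)
        apo = dynamicity_profile(superpose_frames(
            sl.simulate_trajectory(apo_cfg)[0]))
        holo = dynamicity_profile(superpose_frames(
            sl.simulate_trajectory(holo_cfg)[0]))
        ratios = relative_dynamicity(holo, apo, high_threshold=1.5)
        high = set(ratios.loc[ratios["high"], "atom_index"])
        assert set(loop) <= high
        background = ratios[~ratios["atom_index"].isin(loop)]
        assert background["ratio"].mean() < 1.0

    def test_atom_map_mismatch_raises(self):
        p1 = dynamicity_profile(Trajectory(
            np.random.default_rng(0).normal(size=(10, 4, 3))))
        p2 = dynamicity_profile(Trajectory(
            np.random.default_rng(1).normal(size=(10, 4, 3)),
            residue_ids=[1, 1, 2, 2]))
        with pytest.raises(ValueError):
            relative_dynamicity(p1, p2)
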