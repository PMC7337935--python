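import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from oxtraj import synthetic
from oxtraj.core import NM_PER_UNIT, InMemoryTrajectory
from oxtraj.superposition import (
    DegenerateFitError,
    MeanStructureResult,
    align_config,
    align_trajectory,
    centroid,
    kabsch_fit,
    mean_structure,
    rmsd,
    rmsf,
    superimpose_configs,
)
from oxtraj.synthetic import HelixSpec, NoiseSpec


def random_points(n, seed=0):
    return np.random.default_rng(seed).normal(size=(n, 3))


class TestKabsch:
    def test_identity(self):
        pts = random_points(10)
        tf = kabsch_fit(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_recovers_planted_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(50, 3))
        rot = Rotation.random(random_state=np.random.RandomState(2)).as_matrix()
        trans = rng.normal(size=3)
        target = pts @ rot.T + trans
        tf = kabsch_fit(pts, target)
        np.testing.assert_allclose(tf.rotation, rot, atol=1e-8)
        np.testing.assert_allclose(tf.translation, trans, atol=1e-8)
        assert rmsd(tf.apply(pts), target) < 1e-8

    def test_mirror_target_stays_proper(self):
        pts = random_points(8, seed=3)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        tf = kabsch_fit(pts, mirrored)
        tf.validate()
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0)

    def test_too_few_points(self):
        pts = random_points(2)
        with pytest.raises(DegenerateFitError):
            kabsch_fit(pts, pts)

    def test_collinear_rejected(self):
        pts = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(DegenerateFitError, match="collinear"):
            kabsch_fit(pts, pts)

    def test_against_rotation_grid_bruteforce(self):
        # oracle: exhaustive search over an Euler-angle grid on a 5-point toy
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 3))
        rot = Rotation.from_euler("zyx", [0.4, -0.2, 0.9]).as_matrix()
        target = pts @ rot.T + np.array([1.0, -2.0, 0.5])
        tf = kabsch_fit(pts, target)
        kab = rmsd(tf.apply(pts), target)

        pc = pts - pts.mean(axis=0)
        qc = target - target.mean(axis=0)
        grid = np.linspace(0, 2 * np.pi, 25)
        half = np.linspace(-np.pi / 2, np.pi / 2, 13)
        best = np.inf
        for a in grid:
            for b in half:
                for c in grid:
                    r = Rotation.from_euler("zyx", [a, b, c]).as_matrix()
                    best = min(best, rmsd(pc @ r.T, qc))
        assert kab <= best + 1e-12
        # grid resolution ~ 15 deg; grid optimum must approach the SVD optimum
        assert best - kab < 0.5


class TestAlignTrajectory:
    def test_idempotent(self, duplex10):
        topo, cfg, _ = duplex10
        traj = synthetic.perturb(cfg, NoiseSpec(sigma=0.05, n_frames=5, seed=1), topology=topo)
        once = align_trajectory(traj, 0)
        twice = align_trajectory(once, 0)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.positions, b.positions, atol=1e-10)

    def test_rmsd_non_increasing(self, duplex10):
        topo, cfg, _ = duplex10
        rng = np.random.default_rng(6)
        frames = []
        for k in range(6):
            c = cfg.copy()
            rot = Rotation.random(random_state=np.random.RandomState(k)).as_matrix()
            c.positions = c.positions @ rot.T + rng.normal(size=3)
            c.a1 = c.a1 @ rot.T
            c.a3 = c.a3 @ rot.T
            c.positions += rng.normal(scale=0.05, size=c.positions.shape)
            frames.append(c)
        traj = InMemoryTrajectory(topo, frames)
        aligned = align_trajectory(traj, 0)
        ref = traj[0]
        for k in range(len(traj)):
            assert rmsd(aligned[k].positions, ref.positions) <= rmsd(
                traj[k].positions, ref.positions
            ) + 1e-12

    def test_versors_stay_orthonormal(self, duplex10_traj):
        topo, traj, _ = duplex10_traj
        for frame in align_trajectory(traj, 0):
            frame.validate(topo.n_nucleotides)


class TestMeanStructure:
    def test_identical_frames(self, duplex10):
        topo, cfg, _ = duplex10
        traj = InMemoryTrajectory(topo, [cfg.copy() for _ in range(4)])
        result = mean_structure(traj)
        np.testing.assert_allclose(result.mean.positions, cfg.positions, atol=1e-12)

    def test_rigidly_moved_second_frame(self, duplex10):
        topo, cfg, _ = duplex10
        c2 = cfg.copy()
        rot = Rotation.from_euler("z", 0.7).as_matrix()
        c2.positions = c2.positions @ rot.T + np.array([3.0, 1.0, -2.0])
        c2.a1 = c2.a1 @ rot.T
        c2.a3 = c2.a3 @ rot.T
        traj = InMemoryTrajectory(topo, [cfg, c2])
        result = mean_structure(traj)
        np.testing.assert_allclose(result.mean.positions, cfg.positions, atol=1e-8)

    def test_clt_bound(self, duplex10):
        topo, cfg, _ = duplex10
        sigma = 0.05
        n_frames = 2000
        traj = synthetic.perturb(
            cfg, NoiseSpec(sigma=sigma, n_frames=n_frames, seed=3), topology=topo
        )
        # align to the known ground truth so per-frame fit errors average out
        result = mean_structure(traj, reference=cfg)
        err = np.abs(result.mean.positions - cfg.positions)
        assert err.max() < sigma / np.sqrt(n_frames) * 6

    def test_invariant_to_global_rigid_transform(self, duplex10_traj):
        topo, traj, _ = duplex10_traj
        rot = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        shift = np.array([5.0, -2.0, 1.0])
        moved = []
        for c in traj:
            m = c.copy()
            m.positions = m.positions @ rot.T + shift
            m.a1 = m.a1 @ rot.T
            m.a3 = m.a3 @ rot.T
            moved.append(m)
        r1 = mean_structure(traj)
        r2 = mean_structure(InMemoryTrajectory(topo, moved))
        # means must agree after superposition of the frames' rigid change
        tf = kabsch_fit(r2.mean.positions, r1.mean.positions)
        assert rmsd(tf.apply(r2.mean.positions), r1.mean.positions) < 1e-8

    def test_mean_versors_valid(self, duplex10_traj):
        topo, traj, _ = duplex10_traj
        mean_structure(traj).mean.validate(topo.n_nucleotides)


class TestRMSF:
    def test_zero_noise(self, duplex10):
        topo, cfg, _ = duplex10
        traj = InMemoryTrajectory(topo, [cfg.copy() for _ in range(5)])
        profile, overlay = rmsf(traj, mean_structure(traj))
        np.testing.assert_allclose(profile.values_nm, 0.0, atol=1e-10)
        assert overlay.name == "RMSF (nm)"

    def test_single_frame(self, duplex10):
        topo, cfg, _ = duplex10
        traj = InMemoryTrajectory(topo, [cfg])
        profile, _ = rmsf(traj, mean_structure(traj))
        np.testing.assert_allclose(profile.values_nm, 0.0, atol=1e-10)

    def test_isotropic_noise_recovery(self):
        topo, cfg, _ = synthetic.build_duplex(HelixSpec(n_bp=30))
        sigma = 0.1
        traj = synthetic.perturb(
            cfg, NoiseSpec(sigma=sigma, n_frames=1500, seed=8), topology=topo
        )
        profile, _ = rmsf(traj, mean_structure(traj))
        expected = sigma * np.sqrt(3.0) * NM_PER_UNIT
        assert profile.values_nm.mean() == pytest.approx(expected, rel=0.05)

    def test_reference_choice_has_little_impact(self, duplex10):
        topo, cfg, _ = duplex10
        traj = synthetic.perturb(
            cfg, NoiseSpec(sigma=0.05, n_frames=400, seed=9), topology=topo
        )
        p0, _ = rmsf(traj, mean_structure(traj, reference=0))
        p7, _ = rmsf(traj, mean_structure(traj, reference=7))
        np.testing.assert_allclose(p0.values_nm, p7.values_nm, rtol=0.02)


class TestCentroid:
    def test_reference_in_trajectory(self, duplex10_traj):
        topo, traj, _ = duplex10_traj
        idx, _ = centroid(traj, traj[4])
        assert idx == 4

    def test_two_state_reference(self, duplex10):
        topo, cfg, _ = duplex10
        other = synthetic.bent_copy(cfg, 90.0)
        traj, labels = synthetic.two_state_trajectory(
            cfg, other, 0.5, 0.02, 40, seed=10, topology=topo
        )
        idx, _ = centroid(traj, cfg)
        assert labels[idx] == 0

    def test_exhaustive_oracle(self, duplex10):
        topo, cfg, _ = duplex10
        traj = synthetic.perturb(
            cfg, NoiseSpec(sigma=0.08, n_frames=20, seed=11), topology=topo
        )
        idx, _ = centroid(traj, cfg)
        vals = []
        for k in range(len(traj)):
            aligned = align_config(traj[k], cfg)
            vals.append(rmsd(aligned.positions, cfg.positions))
        assert idx == int(np.argmin(vals))


class TestSuperimposeConfigs:
    def test_single_unchanged(self, duplex10):
        _, cfg, _ = duplex10
        out = superimpose_configs([cfg])
        assert out[0] is cfg

    def test_rotated_copies_converge(self, duplex10):
        _, cfg, _ = duplex10
        configs = [cfg]
        for k in range(3):
            c = cfg.copy()
            rot = Rotation.random(random_state=np.random.RandomState(20 + k)).as_matrix()
            c.positions = c.positions @ rot.T + k
            c.a1 = c.a1 @ rot.T
            c.a3 = c.a3 @ rot.T
            configs.append(c)
        out = superimpose_configs(configs)
        for c in out[1:]:
            np.testing.assert_allclose(c.positions, cfg.positions, atol=1e-8)

    def test_mismatched_n_rejected(self, duplex10):
        _, cfg, _ = duplex10
        _, small, _ = synthetic.build_duplex(HelixSpec(n_bp=5))
        with pytest.raises(ValueError):
            superimpose_configs([cfg, small])
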