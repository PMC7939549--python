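"""Rigid registration, complete-track filtering, hull volumes and MSD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy.spatial.transform import Rotation
from scipy.stats import mannwhitneyu

from _oracles import hull_volume_bruteforce, msd_double_loop
from lamindyn import synthetic as syn
from lamindyn import trajectory as tj


def _tracks_from_array(xyz_by_tel, t=None):
    m, n, _ = xyz_by_tel.shape
    if t is None:
        t = np.arange(n, dtype=float)
    return [tj.Trajectory3D(i, 0, t, xyz_by_tel[i]) for i in range(m)]


class TestRegisterFrames:
    def test_static_constellation_gives_identity(self, rng):
        pts = rng.uniform(-2, 2, (5, 3))
        xyz = np.repeat(pts[:, None, :], 4, axis=1)
        _, transforms = tj.register_frames(_tracks_from_array(xyz))
        for tf in transforms:
            assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
            assert np.allclose(tf.translation, 0.0, atol=1e-9)

    def test_known_rigid_motion_recovered_exactly(self, rng):
        pts = rng.uniform(-2, 2, (6, 3))
        R = Rotation.from_euler("zyx", [20, -10, 35], degrees=True).as_matrix()
        v = np.array([0.5, -1.2, 0.3])
        xyz = np.stack([pts, pts @ R.T + v], axis=1)
        corrected, transforms = tj.register_frames(_tracks_from_array(xyz))
        # the recovered transform must invert (R, v) ...
        tf = transforms[1]
        assert np.allclose(tf.rotation @ R, np.eye(3), atol=1e-9)
        assert np.allclose(tf.rotation @ v + tf.translation, 0.0, atol=1e-9)
        assert abs(np.linalg.det(tf.rotation) - 1.0) < 1e-9
        # ... restoring every point to its frame-0 position
        for tr in corrected:
            assert np.allclose(tr.xyz[1], tr.xyz[0], atol=1e-9)

    def test_noise_leaves_bounded_residual(self, rng):
        sigma = 0.01
        pts = rng.uniform(-2, 2, (30, 3))
        R = Rotation.from_euler("z", 15, degrees=True).as_matrix()
        moved = pts @ R.T + np.array([0.3, 0.1, -0.2])
        noisy = moved + rng.normal(0, sigma, moved.shape)
        xyz = np.stack([pts, noisy], axis=1)
        corrected, _ = tj.register_frames(_tracks_from_array(xyz))
        resid = np.stack([tr.xyz[1] - tr.xyz[0] for tr in corrected])
        rms = np.sqrt(np.mean(resid**2))
        assert rms <= 2 * sigma

    def test_underdetermined_frame_left_flagged(self, rng):
        pts = rng.uniform(-1, 1, (2, 3))
        xyz = np.repeat(pts[:, None, :], 3, axis=1)
        _, transforms = tj.register_frames(_tracks_from_array(xyz))
        assert not transforms[1].corrected


class TestFilterComplete:
    def test_missing_frame_excludes_track(self):
        t = np.arange(50, dtype=float)
        full = tj.Trajectory3D(0, 0, t, np.zeros((50, 3)))
        missing = np.zeros(50, dtype=bool)
        missing[13] = True
        partial = tj.Trajectory3D(1, 0, t, np.zeros((50, 3)), missing=missing)
        kept = tj.filter_complete([full, partial], n_required=50)
        assert [tr.telomere_id for tr in kept] == [0]

    def test_empty_input(self):
        assert tj.filter_complete([], n_required=50) == []


class TestHullVolume:
    def test_stationary_point_zero(self):
        xyz = np.zeros((50, 3))
        assert tj.hull_volume(xyz) == 0.0

    def test_unit_tetrahedron_sixth(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        assert tj.hull_volume(pts) == pytest.approx(1 / 6, abs=1e-12)

    def test_coplanar_points_zero(self, rng):
        xy = rng.uniform(0, 1, (20, 2))
        pts = np.column_stack([xy, np.zeros(20)])
        assert tj.hull_volume(pts) == 0.0

    def test_agrees_with_facet_enumeration_oracle(self, rng):
        for _ in range(5):
            pts = np.cumsum(rng.normal(0, 0.1, (50, 3)), axis=0)
            assert tj.hull_volume(pts) == pytest.approx(
                hull_volume_bruteforce(pts), abs=1e-9)

    @given(hst.integers(0, 10_000))
    def test_invariant_under_rigid_transforms(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 1, (15, 3))
        R = Rotation.random(rng=np.random.default_rng(seed + 1)).as_matrix()
        v = rng.uniform(-5, 5, 3)
        assert tj.hull_volume(pts @ R.T + v) == pytest.approx(
            tj.hull_volume(pts), rel=1e-9)


class TestMSD:
    def test_stationary_identically_zero(self):
        t = np.arange(10, dtype=float)
        traj = tj.Trajectory3D(0, 0, t, np.ones((10, 3)))
        _, curve = tj.msd(traj)
        assert np.all(curve == 0.0)

    def test_pure_drift_quadratic(self):
        v = np.array([0.1, -0.2, 0.05])
        t = np.arange(20, dtype=float)
        traj = tj.Trajectory3D(0, 0, t, np.outer(t, v))
        lags, curve = tj.msd(traj)
        assert np.allclose(curve, np.sum(v**2) * lags**2, rtol=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        xyz = np.cumsum(rng.normal(0, 0.2, (30, 3)), axis=0)
        traj = tj.Trajectory3D(0, 0, np.arange(30, dtype=float), xyz)
        _, curve = tj.msd(traj)
        assert np.allclose(curve, msd_double_loop(xyz), rtol=1e-12)

    def test_free_diffusion_slope_recovers_D(self):
        D = 5e-4
        cfg = syn.SyntheticTrajectoryConfig(D_true=D, n_telomeres=150, seed=8)
        trajs, _ = syn.gen_trajectories(cfg)
        curves = np.stack([tj.msd(tr)[1] for tr in trajs])
        lags = tj.msd(trajs[0])[0]
        mean_curve = curves.mean(axis=0)
        slope = np.polyfit(lags[:6], mean_curve[:6], 1)[0]
        assert slope / 6.0 == pytest.approx(D, rel=0.2)


class TestPopulationCurves:
    def test_identical_tracks_zero_band(self):
        t = np.arange(10, dtype=float)
        xyz = np.cumsum(np.ones((10, 3)) * 0.1, axis=0)
        summaries = [tj.summarize(tj.Trajectory3D(i, 0, t, xyz))
                     for i in range(5)]
        pop = tj.population_curves(summaries)
        assert np.allclose(pop["lo"], pop["hi"])
        assert pop["hull_box"]["whisker_lo"] == pop["hull_box"]["whisker_hi"]

    def test_band_brackets_mean_for_symmetric_population(self):
        cfg = syn.SyntheticTrajectoryConfig(D_true=1e-3, n_telomeres=120,
                                            seed=4)
        trajs, _ = syn.gen_trajectories(cfg)
        summaries = [tj.summarize(tr) for tr in trajs]
        pop = tj.population_curves(summaries)
        inside = (pop["mean"][1:] >= pop["lo"][1:]) & \
                 (pop["mean"][1:] <= pop["hi"][1:])
        assert inside.mean() > 0.9

    def test_twofold_mobility_difference_separates_hull_volumes(self):
        def volumes(D, seed):
            out = []
            for s in range(3):
                cfg = syn.SyntheticTrajectoryConfig(
                    D_true=D, n_telomeres=34, seed=seed + s)
                trajs, _ = syn.gen_trajectories(cfg)
                out += [tj.hull_volume(tr) for tr in trajs]
            return np.array(out[:100])

        fast = volumes(1e-3, seed=10)
        slow = volumes(5e-4, seed=20)
        assert mannwhitneyu(fast, slow, alternative="two-sided").pvalue < 0.01
        assert np.median(fast) > np.median(slow)

    def test_single_track_rejected(self):
        t = np.arange(5, dtype=float)
        s = tj.summarize(tj.Trajectory3D(0, 0, t, np.zeros((5, 3))))
        with pytest.raises(ValueError):
            tj.population_curves([s])


class TestRegistrationRecoversMotionVolume:
    def test_drift_contaminated_hulls_recovered(self):
        ratios = []
        for s in range(3):
            cfg = syn.SyntheticTrajectoryConfig(
                seed=s, D_true=5e-4, drift_velocity=0.002,
                rotation_rate=0.0005, n_telomeres=34)
            trajs, truth = syn.gen_trajectories(cfg)
            corrected, _ = tj.register_frames(trajs)
            clean = truth.extra["clean_xyz"]
            for i, tr in enumerate(corrected):
                ratios.append(tj.hull_volume(tr) / tj.hull_volume(clean[i]))
        assert abs(np.median(ratios) - 1.0) < 0.1
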