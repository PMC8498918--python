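"""Triangulation routes: linear SVD, RANSAC pairs, regularized optimization."""

import numpy as np
import pytest

from ringpose.camera import CameraParameters, CameraRig, project
from ringpose.synthetic import (
    make_walker_skeleton,
    simulate_articulated_walker,
    simulate_detections,
    simulate_rig,
)
from ringpose.triangulation import (
    Trajectory3D,
    estimate_derivative,
    median_filter_3d,
    position_angle_errors,
    smooth_series,
    temporal_scale,
    triangulate_linear,
    triangulate_ransac,
    triangulate_regularized,
    triangulate_series,
)


class TestLinear:
    def test_two_camera_exact_recovery(self, clean_rig, rng):
        p = rng.normal(size=3) * 4
        obs = np.full((6, 2), np.nan)
        obs[0] = project(p, clean_rig[0])
        obs[3] = project(p, clean_rig[3])
        est, err = triangulate_linear(obs, clean_rig)
        assert np.allclose(est, p, atol=1e-9)

    def test_orthogonal_axes_ray_intersection_oracle(self):
        """Two cameras with optical axes at 90 degrees: the triangulated
        point must match the hand-computed intersection of the two rays."""
        cam_x = CameraParameters(  # looks along +x from (-10, 0, 0)
            rotation=[0, np.pi / 2, 0], translation=[0, 0, 10.0], focal=500,
            image_size=(640, 480), name="cx",
        )
        cam_z = CameraParameters(  # looks along +z from (0, 0, -10)
            rotation=[0, 0, 0], translation=[0, 0, 10.0], focal=500,
            image_size=(640, 480), name="cz",
        )
        rig = CameraRig([cam_x, cam_z])
        p = np.array([1.0, 0.5, 2.0])
        obs = np.stack([project(p, cam_x), project(p, cam_z)])
        est, err = triangulate_linear(obs, rig)
        # oracle: ray from cam_x center (-10,0,0) through p and ray from
        # cam_z center (0,0,-10) through p intersect exactly at p
        assert np.allclose(est, p, atol=1e-9)
        assert err < 1e-9

    def test_single_view_is_missing(self, clean_rig):
        obs = np.full((6, 2), np.nan)
        obs[2] = [100.0, 100.0]
        est, err = triangulate_linear(obs, clean_rig)
        assert np.isnan(est).all() and np.isnan(err)


class TestMedian3D:
    def test_constant_trajectory_unchanged(self):
        pos = np.tile([1.0, 2.0, 3.0], (20, 2, 1))
        traj = Trajectory3D(pos, ["a", "b"])
        out = median_filter_3d(traj, window=5)
        assert np.allclose(out.positions, pos)

    def test_spike_removed(self):
        pos = np.tile([0.0, 0.0, 0.0], (21, 1, 1))
        pos[10, 0] = [10.0, 10.0, 10.0]
        out = median_filter_3d(Trajectory3D(pos, ["a"]), window=5)
        assert np.allclose(out.positions[10, 0], 0.0)
        # brute-force window median agrees everywhere
        for t in range(21):
            lo, hi = max(0, t - 2), min(21, t + 3)
            assert np.allclose(out.positions[t, 0], np.median(pos[lo:hi, 0], axis=0))

    def test_all_missing_joint_stays_missing(self):
        pos = np.full((10, 1, 3), np.nan)
        out = median_filter_3d(Trajectory3D(pos, ["a"]), window=3)
        assert np.isnan(out.positions).all()


class TestRansac:
    def test_two_views_equal_linear(self, clean_rig, rng):
        p = rng.normal(size=3) * 4
        obs = np.full((6, 2), np.nan)
        obs[1] = project(p, clean_rig[1]) + [1.0, -0.5]
        obs[4] = project(p, clean_rig[4]) + [-0.3, 0.8]
        est_r, _ = triangulate_ransac(obs, clean_rig)
        est_l, _ = triangulate_linear(obs, clean_rig)
        assert np.allclose(est_r, est_l, atol=1e-9)

    def test_corrupted_view_excluded(self, clean_rig, rng):
        p = rng.normal(size=3) * 4
        obs = np.stack([project(p, c) for c in clean_rig])[:4]
        rig4 = CameraRig(list(clean_rig)[:4])
        obs[2] += [50.0, 0.0]
        est_r, _ = triangulate_ransac(obs, rig4)
        est_l, _ = triangulate_linear(obs, rig4)
        assert np.linalg.norm(est_r - p) < np.linalg.norm(est_l - p)
        assert np.linalg.norm(est_r - p) < 1e-6  # clean pair found

    def test_matches_exhaustive_enumeration_oracle(self, clean_rig, rng):
        """Independent pair enumeration reproduces the RANSAC selection."""
        from itertools import combinations

        for _ in range(10):
            p = rng.normal(size=3) * 4
            obs = np.stack([project(p, c) for c in clean_rig])
            obs += rng.normal(0, 3.0, size=obs.shape)
            est, _ = triangulate_ransac(obs, clean_rig)
            best, best_obj = None, np.inf
            for a, b in combinations(range(6), 2):
                pair = np.full_like(obs, np.nan)
                pair[[a, b]] = obs[[a, b]]
                cand, _ = triangulate_linear(pair, clean_rig)
                obj = sum(
                    np.sum((project(cand, clean_rig[i]) - obs[i]) ** 2) for i in (a, b)
                )
                if obj < best_obj:
                    best_obj, best = obj, cand
            assert np.allclose(est, best, atol=1e-12)


class TestTemporalScale:
    def test_reciprocal_mean_displacement_closed_form(self):
        """Constant frame-to-frame displacement of 0.5 units -> gamma = 2."""
        pos = np.zeros((10, 1, 3))
        pos[:, 0, 0] = np.arange(10) * 0.5
        assert temporal_scale(pos) == pytest.approx(2.0)


@pytest.fixture(scope="module")
def walker_scene():
    skeleton = make_walker_skeleton(n_legs=1, joints_per_leg=4)
    traj, skeleton = simulate_articulated_walker(
        skeleton, n_frames=150, frame_rate=100.0, segment_length=10.0,
        body_radius=8.0, seed=4,
    )
    rig = simulate_rig(n_cameras=6, radius=120.0, focal=600.0, k1=0.0)
    return traj, skeleton, rig


class TestRegularized:
    def test_regularizers_off_matches_per_frame_triangulation(self, walker_scene, rng):
        traj, skeleton, rig = walker_scene
        pos, scores = simulate_detections(traj, rig, noise_px=1.0, seed=0)
        obs = pos[:, :30, :, 0, :]
        out = triangulate_regularized(
            obs, rig, skeleton, beta_time=0.0, alpha_limb=0.0,
            robust_norm="linear", max_nfev=100,
        )
        base = triangulate_series(obs, rig, skeleton.joints)
        # with both regularizers off the objective is the per-point
        # reprojection error; refine the linear solution per point as oracle
        from scipy.optimize import least_squares

        for t in range(0, 30, 7):
            for j in range(len(skeleton.joints)):
                o = obs[:, t, j]

                def res(x):
                    r = []
                    for ci, cam in enumerate(rig):
                        if np.isfinite(o[ci]).all():
                            r.append(project(x, cam) - o[ci])
                    return np.concatenate(r)

                ref = least_squares(res, base.positions[t, j]).x
                assert np.allclose(out.positions[t, j], ref, atol=1e-3)

    def test_limb_lengths_recovered_within_two_percent(self, walker_scene):
        traj, skeleton, rig = walker_scene
        pos, _ = simulate_detections(traj, rig, noise_px=2.0, seed=1)
        obs = pos[:, :, :, 0, :]
        out = triangulate_regularized(obs, rig, skeleton, max_nfev=60)
        for limb, length in out.limb_lengths.items():
            assert abs(length - 10.0) / 10.0 < 0.02, (limb, length)

    def test_more_stable_than_linear_triangulation(self, walker_scene):
        """With 2 px detection noise the regularized route must beat plain
        linear triangulation on both limb-length stability and 3D RMSE."""
        traj, skeleton, rig = walker_scene
        pos, _ = simulate_detections(traj, rig, noise_px=2.0, seed=2)
        obs = pos[:, :, :, 0, :]
        reg = triangulate_regularized(obs, rig, skeleton, max_nfev=60)
        lin = triangulate_series(obs, rig, skeleton.joints)
        idx = skeleton.limb_indices()

        def limb_std(tr):
            seg = np.linalg.norm(
                tr.positions[:, idx[:, 0]] - tr.positions[:, idx[:, 1]], axis=-1
            )
            return np.nanstd(seg, axis=0).mean()

        def rmse(tr):
            d = tr.positions - traj.positions
            return np.sqrt(np.nanmean(np.sum(d**2, axis=-1)))

        assert limb_std(reg) < limb_std(lin)
        assert rmse(reg) < rmse(lin)

    def test_acceleration_reduced_relative_to_initialization(self, walker_scene):
        traj, skeleton, rig = walker_scene
        pos, _ = simulate_detections(traj, rig, noise_px=2.0, seed=3)
        obs = pos[:, :80, :, 0, :]
        reg = triangulate_regularized(obs, rig, skeleton, derivative_order=2, max_nfev=60)
        init = triangulate_series(obs, rig, skeleton.joints)

        def msa(tr):
            acc = np.diff(tr.positions, n=2, axis=0)
            return np.nanmean(np.sum(acc**2, axis=-1))

        assert msa(reg) < msa(init)

    def test_reproj_drop_masking_monotone(self, walker_scene):
        traj, skeleton, rig = walker_scene
        pos, _ = simulate_detections(traj, rig, noise_px=2.0, outlier_frac=0.05, seed=5)
        obs = pos[:, :60, :, 0, :]
        counts = []
        for drop in (2.0, 5.0, 20.0, 100.0):
            out = triangulate_regularized(obs, rig, skeleton, reproj_drop=drop, max_nfev=30)
            counts.append(int(out.mask.sum()))
        assert counts == sorted(counts)

    def test_fully_missing_joint_masked_others_solved(self, walker_scene):
        traj, skeleton, rig = walker_scene
        pos, _ = simulate_detections(traj, rig, noise_px=1.0, seed=6)
        obs = pos[:, :40, :, 0, :].copy()
        obs[:, :, 2, :] = np.nan
        out = triangulate_regularized(obs, rig, skeleton, max_nfev=30)
        assert np.isnan(out.positions[:, 2]).all()
        assert np.isfinite(out.positions[:, 0]).any()


class TestSmoothSeries:
    def test_reconstruction_beats_corrupted_input(self):
        from ringpose.synthetic import corrupt_trajectories, simulate_trajectories

        truth = simulate_trajectories(n=10, length=300, cutoff=0.12, seed=8)
        corrupted = corrupt_trajectories(truth, noise_sd=0.3, missing_frac=0.10, seed=9)
        recon = smooth_series(corrupted, beta_time=2.0, derivative_order=2)
        err_in = np.sqrt(np.nanmean((corrupted - truth) ** 2))
        err_out = np.sqrt(np.nanmean((recon - truth) ** 2))
        assert err_out < err_in
        assert np.isfinite(recon).all()  # gaps filled


class TestDerivative:
    def test_constant_position_zero_velocity(self):
        traj = Trajectory3D(np.ones((10, 1, 3)), ["a"], frame_rate=300.0)
        v = estimate_derivative(traj)
        assert np.allclose(v[:-1], 0.0) and np.isnan(v[-1]).all()

    def test_linear_ramp_scaled_by_frame_rate(self):
        pos = np.zeros((10, 1, 3))
        pos[:, 0, 0] = np.arange(10)
        v = estimate_derivative(Trajectory3D(pos, ["a"], frame_rate=300.0))
        assert np.allclose(v[:-1, 0, 0], 300.0)

    def test_missing_propagates(self):
        pos = np.zeros((5, 1, 3))
        pos[2] = np.nan
        v = estimate_derivative(Trajectory3D(pos, ["a"], frame_rate=1.0))
        assert np.isnan(v[1, 0]).all() and np.isnan(v[2, 0]).all()


class TestErrorSummaries:
    def test_identical_inputs_zero_error(self, rng):
        x = rng.normal(size=(50, 3))
        out = position_angle_errors(x, x)
        assert out["mean_error"] == 0.0

    def test_known_offset(self, rng):
        ref = rng.normal(size=(50, 3))
        pred = ref + [2.0, 0.0, 0.0]
        assert position_angle_errors(pred, ref)["mean_error"] == pytest.approx(2.0)

    def test_paired_ci_matches_statistical_oracle(self, rng):
        ref = rng.normal(size=(200, 3))
        a = ref + rng.normal(0, 0.5, size=(200, 3))
        b = ref + rng.normal(0, 1.0, size=(200, 3))
        out = position_angle_errors(a, ref, pred_other=b)
        diff = np.linalg.norm(a - ref, axis=1) - np.linalg.norm(b - ref, axis=1)
        from scipy import stats

        lo, hi = stats.t.interval(0.95, len(diff) - 1, loc=diff.mean(), scale=stats.sem(diff))
        assert out["paired_difference"]["mean"] == pytest.approx(diff.mean())
        assert out["paired_difference"]["ci95"] == pytest.approx([lo, hi])

    def test_empty_overlap_errors(self):
        with pytest.raises(ValueError, match="overlap"):
            position_angle_errors(np.full((5, 3), np.nan), np.zeros((5, 3)))
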