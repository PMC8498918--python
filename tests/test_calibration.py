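"""Calibration: greedy camera graph, initialization, bundle adjustment."""

import numpy as np
import pandas as pd
import pytest

from ringpose._geometry import umeyama_alignment
from ringpose.calibration import (
    BoardGeometry,
    CalibrationError,
    build_camera_graph,
    bundle_adjust,
    calibrate_rig,
    initialize_extrinsics,
    initialize_intrinsics,
    initialize_points3d,
    iterative_bundle_adjust,
    reprojection_errors,
)
from ringpose.synthetic import simulate_board_sequence, simulate_rig


def detections_from_counts(pair_frames):
    """Build a detection table giving each camera pair a set of shared frames."""
    rows = []
    for (a, b), frames in pair_frames.items():
        for f in frames:
            for cam in (a, b):
                for cid in range(4):
                    rows.append((cam, f, cid, 10.0 * cid, 5.0 * cid))
    df = pd.DataFrame(rows, columns=["camera", "frame", "corner_id", "x", "y"])
    return df.drop_duplicates(["camera", "frame", "corner_id"])


class TestCameraGraph:
    def test_two_cameras_single_edge(self):
        det = detections_from_counts({("A", "B"): range(3)})
        g = build_camera_graph(det)
        assert g.spanning_edges == [("A", "B")]

    def test_greedy_skips_redundant_edge(self):
        """AB=50 shared frames, BC=40, AC=30: AC is skipped because A and C
        are already connected through B when its turn comes."""
        det = detections_from_counts(
            {("A", "B"): range(0, 50), ("B", "C"): range(100, 140), ("A", "C"): range(200, 230)}
        )
        g = build_camera_graph(det)
        assert sorted(g.spanning_edges) == [("A", "B"), ("B", "C")]
        assert g.weights[("A", "B")] >= 50  # AC frames also seen by A alone

    def test_disconnected_graph_names_components(self):
        det = detections_from_counts({("A", "B"): range(5), ("C", "D"): range(100, 105)})
        with pytest.raises(CalibrationError, match=r"\['A', 'B'\].*\['C', 'D'\]"):
            build_camera_graph(det)


@pytest.fixture(scope="module")
def clean_sequence():
    rig = simulate_rig(n_cameras=6, radius=120.0, focal=600.0, k1=0.0)
    board = BoardGeometry(6, 6, square_size=5.0, marker_size=3.75)
    det, truth = simulate_board_sequence(rig, board, n_frames=60, noise_px=0.0, seed=7)
    sizes = {c.name: c.image_size for c in rig}
    return rig, board, det, truth, sizes


class TestInitialization:
    def test_focal_recovered_within_one_percent(self, clean_sequence):
        rig, board, det, _truth, sizes = clean_sequence
        focals = initialize_intrinsics(det, board, sizes)
        for name, f in focals.items():
            assert abs(f - 600.0) / 600.0 < 0.01, (name, f)

    def test_fronto_parallel_views_fall_back(self, caplog):
        """Boards facing the camera head-on leave the focal unconstrained."""
        import logging

        from ringpose.camera import CameraParameters, project

        cam = CameraParameters(rotation=[0, 0, 0], translation=[0, 0, 50.0],
                               focal=600.0, image_size=(832, 632))
        board = BoardGeometry(6, 6, square_size=5.0, marker_size=3.75)
        rows = []
        for f, shift in enumerate(np.linspace(-5, 5, 8)):
            pts = board.canonical_corners() + [shift, shift / 2, 0.0]
            uv = project(pts, cam)
            for cid, (x, y) in enumerate(uv):
                rows.append(("cam0", f, cid, x, y))
        det = pd.DataFrame(rows, columns=["camera", "frame", "corner_id", "x", "y"])
        with caplog.at_level(logging.WARNING, logger="ringpose.calibration"):
            focals = initialize_intrinsics(det, board, {"cam0": (832, 632)})
        assert focals["cam0"] == 832.0  # FOV-prior fallback
        assert any("fall" in r.message for r in caplog.records)

    def test_extrinsics_recovered_up_to_rigid_transform(self, clean_sequence):
        rig, board, det, _truth, sizes = clean_sequence
        graph = build_camera_graph(det)
        focals = {n: 600.0 for n in sizes}
        rig0 = initialize_extrinsics(graph, det, board, focals, sizes)
        est = np.array([c.camera_center for c in rig0])
        true = np.array([c.camera_center for c in rig])
        s, R, t = umeyama_alignment(est, true)
        resid = np.abs(s * est @ R.T + t - true).max()
        assert resid < 1e-6

    def test_two_camera_init_reprojects_exactly(self):
        rig = simulate_rig(n_cameras=2, radius=120.0, focal=600.0, k1=0.0)
        board = BoardGeometry(6, 6, square_size=5.0, marker_size=3.75)
        det, _ = simulate_board_sequence(rig, board, n_frames=30, noise_px=0.0, seed=3)
        sizes = {c.name: c.image_size for c in rig}
        graph = build_camera_graph(det)
        rig0 = initialize_extrinsics(graph, det, board, {n: 600.0 for n in sizes}, sizes)
        pts = initialize_points3d(rig0, det, board)
        errs = reprojection_errors(rig0, det, pts)
        assert np.nanmean(errs) < 1e-6


class TestReprojectionErrors:
    def test_noiseless_at_truth_is_zero(self, clean_sequence):
        rig, _board, det, truth, _sizes = clean_sequence
        errs = reprojection_errors(rig, det, truth["points3d"])
        assert np.nanmax(errs) < 1e-9

    def test_uniform_shift_forces_equal_residuals(self, clean_sequence):
        rig, _board, det, truth, _sizes = clean_sequence
        shifted = det.copy()
        shifted["x"] += 3.0
        errs = reprojection_errors(rig, shifted, truth["points3d"])
        assert np.allclose(errs.dropna(), 3.0, atol=1e-9)


class TestBundleAdjust:
    def test_ground_truth_is_fixed_point(self, clean_sequence):
        rig, board, det, truth, _sizes = clean_sequence
        rig2, _pts, summary = bundle_adjust(rig, det, board, points3d=truth["points3d"])
        assert summary.final_error < 1e-9
        for a, b in zip(rig, rig2):
            assert np.allclose(a.to_vector(), b.to_vector(), atol=1e-8)

    def test_perturbed_rig_recovers_ground_truth(self, clean_sequence):
        rig, board, det, truth, _sizes = clean_sequence
        rng = np.random.default_rng(0)
        from dataclasses import replace

        perturbed = [
            replace(
                c,
                rotation=c.rotation + rng.normal(0, np.radians(5) / np.sqrt(3), 3),
                translation=c.translation * (1 + rng.normal(0, 0.02, 3)),
            )
            for c in rig
        ]
        from ringpose.camera import CameraRig

        rig2, _pts, summary = bundle_adjust(
            CameraRig(perturbed), det, board, points3d=truth["points3d"]
        )
        assert summary.final_error < 1e-6
        est = np.array([c.camera_center for c in rig2])
        true = np.array([c.camera_center for c in rig])
        s, R, t = umeyama_alignment(est, true)
        assert np.abs(s * est @ R.T + t - true).max() < 1e-5

    @pytest.mark.parametrize("loss", ["linear", "huber", "soft_l1"])
    def test_robust_losses_accepted_and_monotone(self, clean_sequence, loss):
        rig, board, det, truth, _sizes = clean_sequence
        noisy = det.copy()
        rng = np.random.default_rng(1)
        noisy[["x", "y"]] += rng.normal(0, 0.5, size=(len(det), 2))
        rig2, _pts, summary = bundle_adjust(
            rig, noisy, board, loss=loss, points3d=truth["points3d"], max_nfev=20
        )
        assert summary.final_error <= summary.initial_error + 1e-12


class TestIterativeBundleAdjust:
    def test_noiseless_converges_to_zero_error(self, clean_sequence):
        rig, board, det, _truth, sizes = clean_sequence
        graph = build_camera_graph(det)
        rig0 = initialize_extrinsics(graph, det, board, {n: 600.0 for n in sizes}, sizes)
        rig1, _pts, summary = iterative_bundle_adjust(rig0, det, board, seed=0)
        assert summary.final_error < 1e-6

    def test_outliers_handled_better_than_plain_least_squares(self):
        """5% outliers of 30 px: the decaying-threshold scheme must beat a
        single linear-loss bundle adjustment on inlier reprojection error."""
        rig = simulate_rig(n_cameras=4, radius=120.0, focal=600.0, k1=0.0)
        board = BoardGeometry(6, 6, square_size=5.0, marker_size=3.75)
        det, truth = simulate_board_sequence(
            rig, board, n_frames=60, noise_px=0.5, outlier_frac=0.05, outlier_px=30.0, seed=11
        )
        clean_det, _ = simulate_board_sequence(rig, board, n_frames=60, noise_px=0.0, seed=11)
        sizes = {c.name: c.image_size for c in rig}
        graph = build_camera_graph(det)
        focals = initialize_intrinsics(det, board, sizes)
        rig0 = initialize_extrinsics(graph, det, board, focals, sizes)
        pts0 = initialize_points3d(rig0, det, board)

        rig_it, _pts_it, _ = iterative_bundle_adjust(rig0, det, board, seed=0)
        rig_lin, _pts_lin, _ = bundle_adjust(rig0, det, board, loss="linear", points3d=pts0)

        def rig_quality(rig_x):
            """Mean reprojection error of outlier-free detections triangulated
            with the rig under test: zero iff the rig is self-consistent."""
            from ringpose.triangulation import triangulate_linear

            errs = []
            for (_f, _c), grp in clean_det.groupby(["frame", "corner_id"]):
                obs = np.full((len(rig_x), 2), np.nan)
                for _, row in grp.iterrows():
                    obs[rig_x.names.index(row["camera"])] = (row["x"], row["y"])
                _p, err = triangulate_linear(obs, rig_x)
                if np.isfinite(err):
                    errs.append(err)
            return np.mean(errs)

        assert rig_quality(rig_it) < rig_quality(rig_lin)


class TestFullCalibration:
    def test_noisy_rig_calibrates_below_quality_bar(self):
        rig = simulate_rig(n_cameras=6, radius=120.0, focal=600.0, k1=-0.02)
        board = BoardGeometry(6, 6, square_size=5.0, marker_size=3.75)
        det, _ = simulate_board_sequence(rig, board, n_frames=100, noise_px=0.5, seed=2)
        sizes = {c.name: c.image_size for c in rig}
        rig1, _pts, summary = calibrate_rig(det, board, sizes, seed=0)
        assert summary.final_error <= 3.0
        # the board's known square size anchors the metric scale: aligning the
        # recovered camera centers to the truth needs no residual scaling
        est = np.array([c.camera_center for c in rig1])
        true = np.array([c.camera_center for c in rig])
        s, R, t = umeyama_alignment(est, true)
        assert abs(s - 1.0) < 0.01
        assert np.abs(s * est @ R.T + t - true).max() < 0.02 * 120.0
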