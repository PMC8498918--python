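"""End-to-end quality benchmarks on fully synthetic scenes.

Each benchmark builds a scene with the generators in
:mod:`ringpose.synthetic`, runs the actual pipeline code (calibration,
triangulation), and measures quality against the known ground truth:

- :func:`calibration_benchmark` — mean reprojection error of board corners
  after graph initialization plus iterative bundle adjustment on a 6-camera
  ring with sub-pixel detection noise;
- :func:`charuco_benchmark` — physical accuracy of a reconstructed
  miniature calibration board (2 x 2 mm pattern of 0.5 mm squares, 9
  tracked corners): inter-corner length and corner-triplet angle errors of
  linear-least-squares triangulations through a rig calibrated by the
  package itself.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .calibration import BoardGeometry, calibrate_rig
from .synthetic import simulate_board_sequence, simulate_rig
from .triangulation import triangulate_linear


def calibration_benchmark(
    n_cameras: int = 6,
    n_frames: int = 300,
    noise_px: float = 0.5,
    seed: int = 0,
) -> dict:
    """Calibrate a simulated rig and report the mean reprojection error (px).

    6 cameras (832 x 632 px, ~600 px focal, mild radial distortion) evenly
    spaced around a smoothly moving 6 x 6-square board; Gaussian detection
    noise; iterative bundle adjustment with default settings (12 iterations,
    thresholds decaying 15 -> 1 px).
    """
    seq = np.random.SeedSequence(seed)
    s_scene, s_cal = seq.spawn(2)
    rig = simulate_rig(n_cameras=n_cameras, radius=120.0, focal=600.0, k1=-0.02)
    board = BoardGeometry(6, 6, square_size=5.0, marker_size=3.75)
    det, _truth = simulate_board_sequence(
        rig, board, n_frames=n_frames, noise_px=noise_px, seed=s_scene
    )
    sizes = {c.name: c.image_size for c in rig}
    _rig1, _pts, summary = calibrate_rig(det, board, sizes, seed=s_cal)
    return {
        "mean_reprojection_error_px": summary.final_error,
        "n_observations": summary.n_observations,
    }


def tracked_corner_ids(board: BoardGeometry) -> np.ndarray:
    """9 corners in a 3 x 3 pattern over the interior grid (the tracked
    subset of a 6 x 6-square board)."""
    nx = board.squares_x - 1
    picks = [0, nx // 2, nx - 1]
    return np.array([iy * nx + ix for iy in picks for ix in picks])


def charuco_benchmark(
    n_poses: int = 200,
    noise_px: float = 1.0,
    n_cameras: int = 6,
    seed: int = 0,
) -> dict:
    """Physical length/angle accuracy of a triangulated miniature board.

    The 2 x 2 mm pattern (0.5 mm squares) is viewed by a 6-camera ring at a
    working distance where it spans ~300 px; corner detections carry 1 px
    Gaussian noise over ``n_poses`` board poses.  The rig is calibrated from
    those detections by the package's own pipeline, the 9 tracked corners
    are triangulated linearly, and the 90th percentiles of the absolute
    inter-corner length error (micrometres) and corner-triplet angle error
    (degrees) are reported against the known geometry.
    """
    seq = np.random.SeedSequence(seed)
    s_scene, s_cal = seq.spawn(2)
    board = BoardGeometry(6, 6, square_size=0.5, marker_size=0.375)
    # working distance ~4 mm: 2 mm corner span x 600 px focal -> ~300 px
    rig = simulate_rig(n_cameras=n_cameras, radius=4.0, focal=600.0, k1=-0.02)
    det, _truth = simulate_board_sequence(
        rig, board, n_frames=n_poses, noise_px=noise_px, seed=s_scene
    )
    sizes = {c.name: c.image_size for c in rig}
    rig1, _pts, _summary = calibrate_rig(det, board, sizes, seed=s_cal)

    ids = tracked_corner_ids(board)
    canon = board.canonical_corners(ids)
    cam_index = {n: i for i, n in enumerate(rig1.names)}
    id_pos = {int(c): k for k, c in enumerate(ids)}

    # triangulate the tracked corners per frame
    points = {}
    sub = det[det["corner_id"].isin(ids)]
    for (frame, cid), grp in sub.groupby(["frame", "corner_id"]):
        obs = np.full((len(rig1), 2), np.nan)
        obs[grp["camera"].map(cam_index).to_numpy()] = grp[["x", "y"]].to_numpy(float)
        p, _err = triangulate_linear(obs, rig1)
        if np.isfinite(p).all():
            points.setdefault(int(frame), {})[int(cid)] = p

    pairs = list(combinations(range(len(ids)), 2))
    true_len = {p: np.linalg.norm(canon[p[0]] - canon[p[1]]) for p in pairs}
    triplets = [
        t for t in combinations(range(len(ids)), 3) if _triplet_angles(canon, t) is not None
    ]
    length_errors, angle_errors = [], []
    for frame, got in points.items():
        have = {id_pos[c]: p for c, p in got.items()}
        for a, b in pairs:
            if a in have and b in have:
                est = np.linalg.norm(have[a] - have[b])
                length_errors.append(abs(est - true_len[(a, b)]))
        for t in triplets:
            if all(k in have for k in t):
                est = _triplet_angles(np.array([have[t[0]], have[t[1]], have[t[2]]]), (0, 1, 2))
                true = _triplet_angles(canon, t)
                if est is not None:
                    angle_errors.append(np.max(np.abs(np.asarray(est) - np.asarray(true))))
    length_errors = np.asarray(length_errors) * 1000.0  # mm -> um
    angle_errors = np.asarray(angle_errors)
    return {
        "p90_length_error_um": float(np.percentile(length_errors, 90)),
        "p90_angle_error_deg": float(np.percentile(angle_errors, 90)),
        "n_lengths": int(len(length_errors)),
        "n_angles": int(len(angle_errors)),
    }


def _triplet_angles(pts: np.ndarray, t: tuple) -> tuple | None:
    """The three vertex angles (degrees) of a triangle, or None if the
    points are (near-)collinear."""
    a, b, c = (np.asarray(pts[i], dtype=float) for i in t)
    out = []
    for p, q, r in ((a, b, c), (b, c, a), (c, a, b)):
        u, v = q - p, r - p
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            return None
        cosang = np.clip(u @ v / (nu * nv), -1, 1)
        out.append(np.degrees(np.arccos(cosang)))
    if min(out) < 1.0:  # collinear triplet: angles unstable by construction
        return None
    return tuple(out)
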