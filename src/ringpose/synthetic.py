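"""Synthetic scenes for testing every stage of the pipeline without video.

Generators for: a ring of perspective cameras with radial distortion aimed
at a common working volume; a planar calibration board moved smoothly
through that volume with corrupted corner detections; band-limited smooth
test trajectories; rigid articulated walkers driven by sinusoidal gait
angles; and corrupted multi-camera keypoint detections (Gaussian jitter,
teleporting outliers, missing points, spurious duplicate candidates).

Every generator is deterministic under its seed and returns the ground
truth alongside the corrupted observations, so corruption statistics are
recoverable and reconstructions can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, welch
from scipy.spatial.transform import Rotation

from .calibration import BoardGeometry
from .camera import CameraParameters, CameraRig, look_at_rotation
from .camera import project as _project
from .kinematics import forward_kinematics
from .triangulation import Skeleton, Trajectory3D


def simulate_rig(
    n_cameras: int = 6,
    radius: float = 120.0,
    elevation_deg: float = 15.0,
    image_size: tuple[int, int] = (832, 632),
    focal: float = 600.0,
    k1: float = -0.02,
    seed: int | np.random.SeedSequence | None = 0,
) -> CameraRig:
    """Cameras evenly spaced on a ring, all aimed at the origin.

    Camera centers sit at ``radius`` from the vertical axis, elevated by
    ``elevation_deg``; optical axes pass through the origin, so the working
    volume projects near every image center.
    """
    if n_cameras < 1:
        raise ValueError("need at least one camera")
    del seed  # geometry is deterministic; accepted for interface uniformity
    h = radius * np.tan(np.radians(elevation_deg))
    cams = []
    for i in range(n_cameras):
        theta = 2 * np.pi * i / n_cameras
        center = np.array([radius * np.cos(theta), radius * np.sin(theta), h])
        R = look_at_rotation(center, np.zeros(3))
        t = -R @ center
        cams.append(
            CameraParameters(
                rotation=Rotation.from_matrix(R).as_rotvec(),
                translation=t,
                focal=focal,
                image_size=image_size,
                k1=k1,
                name=f"cam{i}",
            )
        )
    return CameraRig(cams)


def smooth_noise(
    n_series: int,
    length: int,
    cutoff: float,
    rng: np.random.Generator,
    order: int = 4,
) -> np.ndarray:
    """Unit-variance band-limited noise: zero-phase low-passed white noise."""
    if not 0 < cutoff < 0.5:
        raise ValueError("cutoff must be in (0, 0.5) cycles/sample")
    white = rng.standard_normal((n_series, length))
    b, a = butter(order, cutoff * 2)  # Wn in half-cycles/sample
    padlen = min(3 * (order + 1), max(length - 2, 0))
    x = filtfilt(b, a, white, axis=1, padlen=padlen)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def simulate_board_sequence(
    rig: CameraRig,
    board: BoardGeometry,
    n_frames: int = 300,
    noise_px: float = 0.5,
    outlier_frac: float = 0.0,
    outlier_px: float = 30.0,
    seed: int | np.random.SeedSequence | None = 0,
    motion_cutoff: float = 0.05,
    translation_scale: float | None = None,
    rotation_scale: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """A calibration board moved smoothly through the shared view volume.

    The board pose follows low-pass-filtered noise in (rotation-vector,
    translation) space, keeping it near the rig's common working volume with
    varied tilts.  Corners are projected through every camera; Gaussian
    pixel noise is added, a fraction of detections is displaced by
    ``outlier_px`` in a random direction, and corners falling outside the
    image (or behind a camera) are dropped.

    Returns the detection table ``(camera, frame, corner_id, x, y)`` and a
    ground-truth dict with the true corner positions and noiseless
    projections.
    """
    rng = np.random.default_rng(seed)
    radius = float(np.mean([np.linalg.norm(c.camera_center) for c in rig]))
    if translation_scale is None:
        translation_scale = 0.12 * radius
    motion = smooth_noise(6, n_frames, motion_cutoff, rng)
    rotvecs = motion[:3].T * rotation_scale
    translations = motion[3:].T * translation_scale

    corners = board.canonical_corners()
    n_corners = len(corners)
    true_points = np.empty((n_frames, n_corners, 3))
    for f in range(n_frames):
        R = Rotation.from_rotvec(rotvecs[f]).as_matrix()
        true_points[f] = corners @ R.T + translations[f]

    records = []
    truth_rows = []
    for f in range(n_frames):
        for cid in range(n_corners):
            p = true_points[f, cid]
            truth_rows.append((f, cid, p[0], p[1], p[2]))
    for cam in rig:
        uv_clean = _project(true_points.reshape(-1, 3), cam).reshape(n_frames, n_corners, 2)
        uv = uv_clean + rng.normal(0.0, noise_px, size=uv_clean.shape)
        if outlier_frac > 0:
            out_mask = rng.random((n_frames, n_corners)) < outlier_frac
            angles = rng.uniform(0, 2 * np.pi, size=(n_frames, n_corners))
            offs = outlier_px * np.stack([np.cos(angles), np.sin(angles)], axis=-1)
            uv = np.where(out_mask[..., None], uv + offs, uv)
        w, hgt = cam.image_size
        inside = (
            np.isfinite(uv).all(axis=-1)
            & (uv[..., 0] >= 0)
            & (uv[..., 0] < w)
            & (uv[..., 1] >= 0)
            & (uv[..., 1] < hgt)
        )
        fs, cs = np.nonzero(inside)
        for f, cid in zip(fs, cs):
            records.append((cam.name, int(f), int(cid), uv[f, cid, 0], uv[f, cid, 1]))

    detections = pd.DataFrame(records, columns=["camera", "frame", "corner_id", "x", "y"])
    truth = {
        "points3d": pd.DataFrame(truth_rows, columns=["frame", "corner_id", "x", "y", "z"]),
        "rotvecs": rotvecs,
        "translations": translations,
    }
    return detections, truth


def simulate_trajectories(
    n: int = 30,
    length: int = 500,
    cutoff: float = 0.12,
    seed: int | np.random.SeedSequence | None = 0,
) -> np.ndarray:
    """Smooth unit-variance 1D ground-truth trajectories, (n, length).

    White noise passed through a zero-phase low-pass filter with the given
    cutoff in cycles/sample — the spectral profile used to probe how
    temporal regularization preserves band-limited dynamics.
    """
    rng = np.random.default_rng(seed)
    return smooth_noise(n, length, cutoff, rng)


def corrupt_trajectories(
    traj: np.ndarray,
    noise_sd: float,
    missing_frac: float = 0.10,
    seed: int | np.random.SeedSequence | None = 0,
) -> np.ndarray:
    """Additive white noise plus uniformly random missing samples (NaN)."""
    rng = np.random.default_rng(seed)
    out = np.asarray(traj, dtype=float).copy()
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    if missing_frac > 0:
        out[rng.random(out.shape) < missing_frac] = np.nan
    return out


@dataclass
class GaitParams:
    """Sinusoidal gait pattern for the articulated walker.

    Flexion of every link oscillates about ``flexion_mean`` with amplitude
    ``flexion_amp``; the first link additionally rotates and abducts.  Legs
    are phase-shifted by ``leg_phase_offset`` (anti-phase for two legs, the
    alternating-tripod-like default).
    """

    frequency_hz: float = 2.0
    flexion_mean: float = 120.0
    flexion_amp: float = 25.0
    rotation_amp: float = 20.0
    abduction_amp: float = 10.0
    leg_phase_offset: float = np.pi


def make_walker_skeleton(n_legs: int = 2, joints_per_leg: int = 4) -> Skeleton:
    """Rigid multi-leg skeleton: each leg is one kinematic chain."""
    joints, limbs, chains = [], [], []
    for leg in range(n_legs):
        names = [f"L{leg}_j{k}" for k in range(joints_per_leg)]
        joints.extend(names)
        chains.append(names)
        limbs.extend([(a, b) for a, b in zip(names[:-1], names[1:])])
    return Skeleton(joints=joints, limbs=limbs, chains=chains)


def simulate_articulated_walker(
    skeleton: Skeleton | None = None,
    gait: GaitParams | None = None,
    n_frames: int = 300,
    frame_rate: float = 100.0,
    segment_length: float = 10.0,
    body_radius: float = 8.0,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[Trajectory3D, Skeleton]:
    """Rigid articulated limbs walking with sinusoidal joint angles.

    Joint angles follow sinusoids (per-leg phase offsets, small random
    per-joint phase jitter); positions come from forward kinematics with
    exactly constant segment lengths, so limb-length recovery has an exact
    ground truth.
    """
    if skeleton is None:
        skeleton = make_walker_skeleton()
    if gait is None:
        gait = GaitParams()
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    omega = 2 * np.pi * gait.frequency_hz

    all_pos = []
    for leg, chain in enumerate(skeleton.chains):
        K = len(chain)
        n_triples = K - 2
        phase = leg * gait.leg_phase_offset + rng.uniform(0, 0.3)
        base_angle = 2 * np.pi * leg / max(len(skeleton.chains), 1)
        base = np.array(
            [body_radius * np.cos(base_angle), body_radius * np.sin(base_angle), 0.0]
        )
        # body frame for this leg: z points outward/down so the leg extends away
        z_axis = np.array([np.cos(base_angle), np.sin(base_angle), -0.8])
        z_axis /= np.linalg.norm(z_axis)
        x_axis = np.array([-np.sin(base_angle), np.cos(base_angle), 0.0])
        x_axis = x_axis - (x_axis @ z_axis) * z_axis
        x_axis /= np.linalg.norm(x_axis)
        body = np.column_stack([x_axis, np.cross(z_axis, x_axis), z_axis])

        flexion = np.empty((n_frames, n_triples))
        rotation = np.zeros((n_frames, n_triples))
        abduction = np.zeros((n_frames, n_triples))
        for i in range(n_triples):
            jitter = rng.uniform(-0.2, 0.2)
            flexion[:, i] = gait.flexion_mean + gait.flexion_amp * np.sin(
                omega * t + phase + i * 0.8 + jitter
            )
            if i < n_triples - 1:  # last link's rotation is unobservable
                rotation[:, i] = gait.rotation_amp * np.sin(omega * t + phase + jitter + 1.0)
        abduction[:, 0] = gait.abduction_amp * np.sin(omega * t + phase + 0.5)
        lengths = np.full(K - 1, segment_length)
        pos = forward_kinematics(base, body, lengths, rotation, flexion, abduction)
        all_pos.append(pos)

    positions = np.concatenate(all_pos, axis=1)
    traj = Trajectory3D(positions, list(skeleton.joints), frame_rate)
    return traj, skeleton


def simulate_detections(
    traj: Trajectory3D,
    rig: CameraRig,
    noise_px: float = 2.0,
    outlier_frac: float = 0.0,
    outlier_px: float = 60.0,
    missing_frac: float = 0.0,
    n_candidates: int = 1,
    spurious_score: float = 0.6,
    seed: int | np.random.SeedSequence | None = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupted per-camera keypoint candidates for a ground-truth trajectory.

    Candidate 0 is the true projection with Gaussian jitter (score ~ 0.9);
    with probability ``outlier_frac`` it teleports by ``outlier_px``.  Extra
    candidates are spurious detections scattered around the true point with
    lower scores.  ``missing_frac`` of (camera, frame, joint) entries are
    dropped entirely.

    Returns ``positions (n_cams, T, J, n_cand, 2)`` and matching scores.
    """
    rng = np.random.default_rng(seed)
    T, J, _ = traj.positions.shape
    C = len(rig)
    pos = np.full((C, T, J, n_candidates, 2), np.nan)
    scores = np.full((C, T, J, n_candidates), np.nan)
    for ci, cam in enumerate(rig):
        uv = _project(traj.positions.reshape(-1, 3), cam).reshape(T, J, 2)
        jitter = rng.normal(0, noise_px, size=uv.shape)
        main = uv + jitter
        tele = rng.random((T, J)) < outlier_frac
        ang = rng.uniform(0, 2 * np.pi, size=(T, J))
        off = outlier_px * np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        main = np.where(tele[..., None], main + off, main)
        pos[ci, :, :, 0, :] = main
        scores[ci, :, :, 0] = np.clip(rng.normal(0.9, 0.05, size=(T, J)), 0, 1)
        for k in range(1, n_candidates):
            spread = rng.normal(0, 20 * noise_px + 5, size=uv.shape)
            pos[ci, :, :, k, :] = uv + spread
            scores[ci, :, :, k] = np.clip(
                rng.normal(spurious_score - 0.15 * k, 0.1, size=(T, J)), 0, 1
            )
        if missing_frac > 0:
            drop = rng.random((T, J)) < missing_frac
            pos[ci][drop] = np.nan
            scores[ci][drop] = np.nan
        # keypoints invisible to the camera stay missing
        invisible = ~np.isfinite(uv).all(axis=-1)
        pos[ci][invisible] = np.nan
        scores[ci][invisible] = np.nan
    return pos, scores


def evaluate_reconstruction(
    ground_truth: np.ndarray,
    reconstruction: np.ndarray,
    nperseg: int = 256,
) -> dict:
    """RMSE over non-missing samples plus Welch power spectra.

    Inputs are (n_series, length) arrays; the PSD is averaged across series.
    """
    gt = np.asarray(ground_truth, dtype=float)
    rec = np.asarray(reconstruction, dtype=float)
    if gt.shape != rec.shape:
        raise ValueError("shape mismatch")
    diff = rec - gt
    valid = np.isfinite(diff)
    rmse = float(np.sqrt(np.mean(diff[valid] ** 2))) if valid.any() else np.nan
    out = {"rmse": rmse, "n_valid": int(valid.sum())}
    nperseg = min(nperseg, gt.shape[-1])
    freqs, psd_gt = welch(gt, nperseg=nperseg, axis=-1)
    finite_rec = np.where(np.isfinite(rec), rec, 0.0)
    _, psd_rec = welch(finite_rec, nperseg=nperseg, axis=-1)
    out["freqs"] = freqs
    out["psd_ground_truth"] = psd_gt.mean(axis=0)
    out["psd_reconstruction"] = psd_rec.mean(axis=0)
    return out
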