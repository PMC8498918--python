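"""3D reconstruction from multi-camera 2D keypoints.

Four triangulation routes, in increasing robustness:

- linear least squares (DLT/SVD) per point — fast, outlier-sensitive;
- the same followed by a running median over frames;
- RANSAC-style exhaustive camera-pair search minimizing the two-view
  reprojection error;
- spatiotemporally regularized triangulation, which jointly optimizes all
  3D points and one length parameter per limb under three soft constraints:
  reprojection consistency (robustified), temporal smoothness of order-k
  finite differences, and constancy of limb lengths.

The regularized objective is ``L = L_proj + alpha_time * L_time +
alpha_limb * L_limb`` with ``alpha_time = beta_time * gamma``, where the
scale ``gamma`` is the reciprocal mean frame-to-frame displacement of the
linear-triangulation initialization, making ``beta_time`` unitless and
transferable across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix

from .camera import CameraRig, pixel_to_normalized, project

logger = logging.getLogger(__name__)


@dataclass
class Skeleton:
    """Joint names, limb edges, and kinematic chains of an articulated body.

    ``limbs`` are (joint_a, joint_b) edges whose 3D length is regularized;
    limbs listed in ``flexible`` (e.g. a fly's tarsus or human shoulders)
    get their length residual down-weighted.  ``chains`` are ordered joint
    paths from the body outward used for angle extraction.
    """

    joints: list[str]
    limbs: list[tuple[str, str]] = field(default_factory=list)
    chains: list[list[str]] = field(default_factory=list)
    flexible: list[tuple[str, str]] = field(default_factory=list)
    flexible_weight: float = 0.5

    def __post_init__(self) -> None:
        for a, b in self.limbs:
            if a not in self.joints or b not in self.joints:
                raise ValueError(f"limb ({a}, {b}) references unknown joint")
        for chain in self.chains:
            for j in chain:
                if j not in self.joints:
                    raise ValueError(f"chain joint {j!r} unknown")

    def limb_indices(self) -> np.ndarray:
        idx = {j: i for i, j in enumerate(self.joints)}
        return np.array([[idx[a], idx[b]] for a, b in self.limbs], dtype=int)

    def limb_weights(self) -> np.ndarray:
        flex = {tuple(sorted(l)) for l in self.flexible}
        return np.array(
            [self.flexible_weight if tuple(sorted(l)) in flex else 1.0 for l in self.limbs]
        )


@dataclass
class Trajectory3D:
    """Frames x joints x 3 positions with missing-data mask as NaN."""

    positions: np.ndarray  # (T, J, 3), NaN = missing
    joints: list[str]
    frame_rate: float = 1.0
    reprojection_error: np.ndarray | None = None  # (T, J) px
    n_cams: np.ndarray | None = None  # (T, J)
    limb_lengths: dict[tuple[str, str], float] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (frames, joints, 3)")
        if self.positions.shape[1] != len(self.joints):
            raise ValueError("joint count mismatch")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """(T, J) boolean array: True where the point is present."""
        return np.isfinite(self.positions).all(axis=2)


def _dlt_rows(obs_norm: np.ndarray, rig: CameraRig) -> np.ndarray:
    """Stack DLT rows for one point; obs_norm is (n_cams, 2) undistorted
    normalized coordinates, NaN for missing views."""
    rows = []
    for cam, uv in zip(rig, obs_norm):
        if not np.isfinite(uv).all():
            continue
        R = cam.rotation_matrix
        P = np.column_stack([R, cam.translation])  # 3x4, normalized projection
        rows.append(uv[0] * P[2] - P[0])
        rows.append(uv[1] * P[2] - P[1])
    return np.asarray(rows)


def triangulate_linear(obs: np.ndarray, rig: CameraRig) -> tuple[np.ndarray, float]:
    """DLT triangulation of one point from pixel observations.

    Parameters
    ----------
    obs : (n_cams, 2) array
        Pixel coordinates per camera, NaN where unobserved.

    Returns
    -------
    (point, reprojection_error) — NaN point and error when fewer than two
    cameras observe the point.
    """
    obs = np.asarray(obs, dtype=float)
    valid = np.isfinite(obs).all(axis=1)
    if valid.sum() < 2:
        return np.full(3, np.nan), np.nan
    obs_norm = np.full_like(obs, np.nan)
    for i, cam in enumerate(rig):
        if valid[i]:
            obs_norm[i] = pixel_to_normalized(obs[i], cam)
    A = _dlt_rows(obs_norm, rig)
    if len(A) < 4:
        return np.full(3, np.nan), np.nan
    _, _, vt = np.linalg.svd(A)
    ph = vt[-1]
    if abs(ph[3]) < 1e-14:
        return np.full(3, np.nan), np.nan
    p = ph[:3] / ph[3]
    err = reprojection_error_point(p, obs, rig)
    return p, err


def reprojection_error_point(point: np.ndarray, obs: np.ndarray, rig: CameraRig) -> float:
    """Mean pixel reprojection error of one 3D point over its observed views."""
    errs = []
    for cam, uv in zip(rig, np.asarray(obs, dtype=float)):
        if not np.isfinite(uv).all():
            continue
        proj = project(point, cam)
        errs.append(np.linalg.norm(proj - uv))
    return float(np.mean(errs)) if errs else np.nan


def triangulate_ransac(obs: np.ndarray, rig: CameraRig) -> tuple[np.ndarray, float]:
    """Triangulate one point from the best camera pair.

    Every pair of observing cameras is triangulated linearly and the point
    minimizing the two-view reprojection objective
    ``||T(p, a) - u_a||^2 + ||T(p, b) - u_b||^2`` is returned — an exhaustive
    consensus search that excludes cameras with outlier detections.
    """
    obs = np.asarray(obs, dtype=float)
    valid = np.flatnonzero(np.isfinite(obs).all(axis=1))
    if len(valid) < 2:
        return np.full(3, np.nan), np.nan
    best, best_obj = None, np.inf
    for ii, a in enumerate(valid):
        for b in valid[ii + 1 :]:
            pair_obs = np.full_like(obs, np.nan)
            pair_obs[[a, b]] = obs[[a, b]]
            p, _ = triangulate_linear(pair_obs, rig)
            if not np.isfinite(p).all():
                continue
            obj = (
                np.sum((project(p, rig[int(a)]) - obs[a]) ** 2)
                + np.sum((project(p, rig[int(b)]) - obs[b]) ** 2)
            )
            if obj < best_obj:
                best_obj, best = obj, p
    if best is None:
        return np.full(3, np.nan), np.nan
    return best, reprojection_error_point(best, obs, rig)


def triangulate_series(
    obs: np.ndarray,
    rig: CameraRig,
    joints: list[str] | None = None,
    frame_rate: float = 1.0,
    method: str = "linear",
) -> Trajectory3D:
    """Per-frame triangulation of a (n_cams, T, J, 2) observation array."""
    obs = np.asarray(obs, dtype=float)
    n_cams, T, J, _ = obs.shape
    if n_cams != len(rig):
        raise ValueError("observation array does not match rig size")
    if joints is None:
        joints = [f"joint_{j}" for j in range(J)]
    tri = triangulate_ransac if method == "ransac" else triangulate_linear
    pos = np.full((T, J, 3), np.nan)
    err = np.full((T, J), np.nan)
    ncam = np.zeros((T, J), dtype=int)
    for t in range(T):
        for j in range(J):
            o = obs[:, t, j]
            ncam[t, j] = int(np.isfinite(o).all(axis=1).sum())
            pos[t, j], err[t, j] = tri(o, rig)
    return Trajectory3D(pos, list(joints), frame_rate, err, ncam)


def median_filter_3d(traj: Trajectory3D, window: int = 7) -> Trajectory3D:
    """Running median over frames, per joint and coordinate, NaN-aware."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    T, J, _ = traj.positions.shape
    out = traj.positions.copy()
    for j in range(J):
        df = pd.DataFrame(traj.positions[:, j, :])
        med = df.rolling(window, center=True, min_periods=1).median().to_numpy()
        present = np.isfinite(traj.positions[:, j, :]).all(axis=1)
        out[present, j, :] = med[present]
    return Trajectory3D(
        out, traj.joints, traj.frame_rate, traj.reprojection_error, traj.n_cams, traj.limb_lengths
    )


# --------------------------------------------------------------------------
# spatiotemporally regularized triangulation


def _robustify(r: np.ndarray, norm: str, scale: float) -> np.ndarray:
    """Component-wise sqrt-rho transform so that sum(r_tilde^2) = sum(rho(r))."""
    if norm == "linear":
        return r
    if norm == "soft_l1":
        return np.sign(r) * scale * np.sqrt(2.0 * (np.sqrt(1.0 + (r / scale) ** 2) - 1.0))
    if norm == "huber":
        a = np.abs(r)
        out = np.where(a <= scale, r, np.sign(r) * np.sqrt(scale * (2.0 * a - scale)))
        return out
    raise ValueError(f"unknown robust norm {norm!r}")


def temporal_scale(init_positions: np.ndarray) -> float:
    """gamma = N / sum of frame-to-frame displacement magnitudes.

    The reciprocal mean displacement of the initialization; multiplying the
    temporal loss by it renders ``beta_time`` invariant to the spatial scale
    of the dataset.
    """
    diffs = np.diff(init_positions, axis=0)
    mags = np.linalg.norm(diffs, axis=-1)
    mags = mags[np.isfinite(mags)]
    total = float(np.sum(mags))
    if total <= 0 or len(mags) == 0:
        return 1.0
    return len(mags) / total


def _interpolate_gaps(pos: np.ndarray) -> np.ndarray:
    """Linear interpolation (and edge fill) of NaN runs, per joint/coordinate."""
    T, J, _ = pos.shape
    out = pos.copy()
    for j in range(J):
        df = pd.DataFrame(out[:, j, :])
        df = df.interpolate(limit_direction="both")
        out[:, j, :] = df.to_numpy()
    return out


def _regularized_chunk(
    obs: np.ndarray,
    rig: CameraRig,
    skeleton: Skeleton,
    beta_time: float,
    alpha_limb: float,
    derivative_order: int,
    robust_norm: str,
    robust_scale: float,
    d_init: np.ndarray | None,
    max_nfev: int,
    verbose: int,
) -> tuple[np.ndarray, np.ndarray]:
    n_cams, T, J, _ = obs.shape
    init = triangulate_series(obs, rig).positions
    joint_seen = np.isfinite(init).all(axis=2).any(axis=0)  # (J,)
    gamma = temporal_scale(init)
    alpha_time = beta_time * gamma
    p0 = _interpolate_gaps(init)
    p0 = np.nan_to_num(p0, nan=0.0)

    limb_idx = skeleton.limb_indices() if skeleton.limbs else np.zeros((0, 2), int)
    limb_w = skeleton.limb_weights() if skeleton.limbs else np.zeros(0)
    n_limbs = len(limb_idx)
    if d_init is None and n_limbs:
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN limbs
            lengths = np.linalg.norm(
                init[:, limb_idx[:, 0]] - init[:, limb_idx[:, 1]], axis=-1
            )
            d_init = np.nanmedian(lengths, axis=0)
        d_init = np.where(np.isfinite(d_init) & (d_init > 0), d_init, 1.0)
    elif d_init is None:
        d_init = np.zeros(0)

    # observation bookkeeping
    cam_i, t_i, j_i = np.nonzero(np.isfinite(obs).all(axis=3))
    obs_xy = obs[cam_i, t_i, j_i]

    k = derivative_order
    n_temp = max(T - k, 0)
    sqrt_at = np.sqrt(alpha_time)
    sqrt_al = np.sqrt(alpha_limb)

    def unpack(x):
        p = x[: 3 * T * J].reshape(T, J, 3)
        d = x[3 * T * J :]
        return p, d

    cams = list(rig)

    def residuals(x):
        p, d = unpack(x)
        parts = []
        # reprojection
        res = np.empty((len(obs_xy), 2))
        for ci, cam in enumerate(cams):
            m = cam_i == ci
            if not m.any():
                continue
            uv = project(p[t_i[m], j_i[m]], cam)
            res[m] = uv - obs_xy[m]
        res = np.nan_to_num(res, nan=0.0, posinf=1e6, neginf=-1e6)
        parts.append(_robustify(res, robust_norm, robust_scale).ravel())
        # temporal smoothness
        if n_temp and alpha_time > 0:
            parts.append((sqrt_at * np.diff(p, n=k, axis=0)).ravel())
        # limb lengths
        if n_limbs and alpha_limb > 0:
            seg = np.linalg.norm(p[:, limb_idx[:, 0]] - p[:, limb_idx[:, 1]], axis=-1)
            parts.append((sqrt_al * limb_w * (seg - d) / d).ravel())
        return np.concatenate(parts)

    # sparsity pattern
    n_var = 3 * T * J + n_limbs
    n_res = 2 * len(obs_xy)
    if alpha_time > 0:
        n_res += n_temp * J * 3
    if n_limbs and alpha_limb > 0:
        n_res += T * n_limbs
    A = lil_matrix((n_res, n_var), dtype=int)
    row = np.arange(len(obs_xy))
    for c in range(3):
        cols = 3 * (t_i * J + j_i) + c
        A[2 * row, cols] = 1
        A[2 * row + 1, cols] = 1
    offset = 2 * len(obs_xy)
    if alpha_time > 0 and n_temp:
        r = offset + np.arange(n_temp * J * 3)
        tt, jj, cc = np.unravel_index(np.arange(n_temp * J * 3), (n_temp, J, 3))
        for s in range(k + 1):
            A[r, 3 * ((tt + s) * J + jj) + cc] = 1
        offset += n_temp * J * 3
    if n_limbs and alpha_limb > 0:
        r = offset + np.arange(T * n_limbs)
        tt, ll = np.unravel_index(np.arange(T * n_limbs), (T, n_limbs))
        for c in range(3):
            A[r, 3 * (tt * J + limb_idx[ll, 0]) + c] = 1
            A[r, 3 * (tt * J + limb_idx[ll, 1]) + c] = 1
        A[r, 3 * T * J + ll] = 1

    x0 = np.concatenate([p0.ravel(), d_init])
    result = least_squares(
        residuals,
        x0,
        jac_sparsity=A,
        method="trf",
        ftol=1e-8,
        max_nfev=max_nfev,
        verbose=verbose,
    )
    if result.status <= 0:
        logger.warning("regularized triangulation: solver did not converge (%s)", result.message)
    p, d = unpack(result.x)
    p = p.copy()
    p[:, ~joint_seen] = np.nan
    return p, d


def triangulate_regularized(
    obs: np.ndarray,
    rig: CameraRig,
    skeleton: Skeleton,
    beta_time: float = 2.0,
    alpha_limb: float = 2.0,
    derivative_order: int = 2,
    robust_norm: str = "soft_l1",
    robust_scale: float = 10.0,
    reproj_drop: float = 20.0,
    frame_rate: float = 1.0,
    chunk_size: int = 500,
    chunk_overlap: int = 50,
    max_nfev: int = 30,
    verbose: int = 0,
) -> Trajectory3D:
    """Spatiotemporally regularized triangulation of a full recording.

    Parameters
    ----------
    obs : (n_cams, T, J, 2) array
        Filtered 2D keypoints per camera, NaN where missing.
    skeleton : Skeleton
        Supplies the limb edges whose lengths are regularized (one free
        length ``d_l`` per limb is co-estimated).
    beta_time : float
        Unitless temporal-smoothness weight; the effective weight is
        ``beta_time * gamma`` with gamma the reciprocal mean frame-to-frame
        displacement of the linear initialization.
    alpha_limb : float
        Weight of the normalized limb-length residuals.
    derivative_order : int
        Order of the finite difference penalized by the temporal term.
    reproj_drop : float
        Points with mean reprojection error above this (pixels) are masked
        after optimization.

    Long recordings are processed in overlapping chunks blended linearly,
    keeping memory linear in the number of frames.
    """
    obs = np.asarray(obs, dtype=float)
    n_cams, T, J, _ = obs.shape
    if list(skeleton.joints) and J != len(skeleton.joints):
        raise ValueError("skeleton joint count does not match observations")

    starts = list(range(0, max(T - chunk_overlap, 1), max(chunk_size - chunk_overlap, 1)))
    pos = np.zeros((T, J, 3))
    weight = np.zeros(T)
    d_all = []
    for s in starts:
        e = min(s + chunk_size, T)
        p, d = _regularized_chunk(
            obs[:, s:e],
            rig,
            skeleton,
            beta_time,
            alpha_limb,
            derivative_order,
            robust_norm,
            robust_scale,
            None,
            max_nfev,
            verbose,
        )
        w = np.ones(e - s)
        if s > 0:
            ramp = min(chunk_overlap, e - s)
            w[:ramp] = np.linspace(0, 1, ramp + 2)[1:-1]
        pw = np.where(np.isfinite(p), p, 0.0)
        pos[s:e] += pw * w[:, None, None]
        weight[s:e] += w
        d_all.append(d)
        if e >= T:
            break
    with np.errstate(invalid="ignore", divide="ignore"):
        pos = pos / weight[:, None, None]

    # mask never-observed joints and high-reprojection-error points
    err = np.full((T, J), np.nan)
    ncam_arr = np.isfinite(obs).all(axis=3).sum(axis=0)
    for t in range(T):
        for j in range(J):
            if np.isfinite(pos[t, j]).all():
                err[t, j] = reprojection_error_point(pos[t, j], obs[:, t, j], rig)
    drop = err > reproj_drop
    pos[drop] = np.nan
    never = ~np.isfinite(obs).all(axis=3).any(axis=(0, 1))
    pos[:, never] = np.nan

    limb_lengths = None
    if skeleton.limbs and d_all:
        d_med = np.median(np.asarray(d_all), axis=0)
        limb_lengths = {tuple(l): float(v) for l, v in zip(skeleton.limbs, d_med)}
    return Trajectory3D(pos, list(skeleton.joints) or [f"joint_{j}" for j in range(J)],
                        frame_rate, err, ncam_arr, limb_lengths)


def smooth_series(
    values: np.ndarray,
    beta_time: float = 2.0,
    derivative_order: int = 2,
) -> np.ndarray:
    """Temporal regularization of 1D series with missing samples.

    Solves, per series, the quadratic problem
    ``min_x sum_observed (x_t - y_t)^2 + alpha_time * sum ||D^k x||^2`` with
    ``alpha_time = beta_time * gamma`` and gamma the reciprocal mean
    one-frame displacement of the (interpolated) input — the same temporal
    term and scale convention as :func:`triangulate_regularized`, isolated
    from the camera geometry.  Missing samples (NaN) are reconstructed
    purely from the smoothness term.
    """
    from scipy.sparse import diags, eye
    from scipy.sparse.linalg import spsolve

    y = np.atleast_2d(np.asarray(values, dtype=float))
    n_series, T = y.shape
    k = derivative_order
    # finite-difference operator of order k
    D = eye(T, format="csc")
    for _ in range(k):
        m = D.shape[0]
        D = diags([-1.0, 1.0], [0, 1], shape=(m - 1, m), format="csc") @ D
    out = np.empty_like(y)
    for i in range(n_series):
        obs = np.isfinite(y[i])
        filled = pd.Series(y[i]).interpolate(limit_direction="both").to_numpy()
        gamma = temporal_scale(filled[:, None, None])
        alpha = beta_time * gamma
        W = diags(obs.astype(float))
        A = (W + alpha * (D.T @ D)).tocsc()
        b = np.where(obs, y[i], 0.0)
        out[i] = spsolve(A, b)
    return out[0] if np.asarray(values).ndim == 1 else out


def estimate_derivative(traj: Trajectory3D) -> np.ndarray:
    """One-frame forward difference times the frame rate -> (T, J, 3) velocity.

    The last frame (no forward neighbor) and any frame whose pair contains a
    missing point come back NaN.
    """
    vel = np.full_like(traj.positions, np.nan)
    vel[:-1] = np.diff(traj.positions, axis=0) * traj.frame_rate
    return vel


def position_angle_errors(
    pred: np.ndarray,
    ref: np.ndarray,
    pred_other: np.ndarray | None = None,
) -> dict:
    """Pointwise Euclidean errors against a reference, with paired comparison.

    ``pred`` and ``ref`` are broadcastable (..., d) arrays (3D positions or
    1D angle values in the last axis).  When ``pred_other`` is given, the
    paired per-point error difference (pred - pred_other) is summarized with
    its mean and a t-based 95% confidence interval.
    """
    from scipy import stats

    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref shapes must match")
    if pred.ndim > 1:
        err = np.linalg.norm(pred - ref, axis=-1)
    else:
        err = np.abs(pred - ref)
    valid = np.isfinite(err)
    if not valid.any():
        raise ValueError("no overlapping finite points to compare")
    out = {
        "mean_error": float(np.mean(err[valid])),
        "median_error": float(np.median(err[valid])),
        "p90_error": float(np.percentile(err[valid], 90)),
        "n": int(valid.sum()),
    }
    if pred_other is not None:
        pred_other = np.asarray(pred_other, dtype=float)
        if pred_other.ndim > 1:
            err2 = np.linalg.norm(pred_other - ref, axis=-1)
        else:
            err2 = np.abs(pred_other - ref)
        both = valid & np.isfinite(err2)
        diff = err[both] - err2[both]
        mean = float(np.mean(diff))
        sem = stats.sem(diff)
        lo, hi = stats.t.interval(0.95, len(diff) - 1, loc=mean, scale=sem) if len(diff) > 1 else (np.nan, np.nan)
        out["paired_difference"] = {"mean": mean, "ci95": [float(lo), float(hi)], "n": int(both.sum())}
    return out
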