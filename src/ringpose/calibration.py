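"""Multi-camera calibration from calibration-board corner detections.

The calibration pipeline estimates all camera parameters (extrinsics, focal
length, radial distortion) from tables of detected board corners:

1. intrinsics are initialized per camera from board-plane homographies
   (closed-form single-focal solution), distortion starts at zero;
2. extrinsics are initialized by a greedy camera graph: camera pairs are
   visited in decreasing order of the number of frames in which both see the
   board, and an edge is added whenever it connects two previously
   unconnected cameras, yielding a spanning tree over which relative poses
   propagate from an arbitrary root;
3. bundle adjustment jointly refines all camera parameters and the free 3D
   corner positions by sparse nonlinear least squares on the reprojection
   error, optionally with a robust (Huber / soft-L1) norm;
4. iterative bundle adjustment repeats step 3 on the subset of observations
   whose current reprojection error falls below an exponentially decreasing
   pixel threshold, which suppresses outlier detections without tuning a
   robust-loss scale.

Detections are plain pandas DataFrames with columns
``(camera, frame, corner_id, x, y)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.sparse import lil_matrix

from ._geometry import (
    estimate_homography,
    focal_from_homographies,
    pose_from_homography,
)
from .camera import CameraParameters, CameraRig, project

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["camera", "frame", "corner_id", "x", "y"]

#: minimum observations per free parameter before bundle adjustment runs
MIN_OBS_PER_PARAM = 10


class CalibrationError(RuntimeError):
    pass


@dataclass
class BoardGeometry:
    """Planar calibration board: a grid of squares with known spacing.

    The tracked keypoints are the interior corners of the checkerboard,
    indexed row-major; their canonical 3D coordinates lie on the z = 0 plane,
    centered on the board, with spacing ``square_size``.
    """

    squares_x: int = 6
    squares_y: int = 6
    square_size: float = 0.5
    marker_size: float = 0.375
    tracked_corner_ids: list[int] | None = None

    def __post_init__(self) -> None:
        if not (0 < self.marker_size < self.square_size):
            raise ValueError("require 0 < marker_size < square_size")
        if self.squares_x < 2 or self.squares_y < 2:
            raise ValueError("board needs at least 2x2 squares")

    @property
    def n_corners(self) -> int:
        return (self.squares_x - 1) * (self.squares_y - 1)

    @property
    def corner_ids(self) -> np.ndarray:
        if self.tracked_corner_ids is not None:
            return np.asarray(self.tracked_corner_ids, dtype=int)
        return np.arange(self.n_corners)

    def canonical_corners(self, ids: np.ndarray | None = None) -> np.ndarray:
        """(n, 3) canonical corner coordinates on the z=0 board plane."""
        nx, ny = self.squares_x - 1, self.squares_y - 1
        if ids is None:
            ids = np.arange(self.n_corners)
        ids = np.asarray(ids, dtype=int)
        ix = ids % nx
        iy = ids // nx
        x = (ix - (nx - 1) / 2.0) * self.square_size
        y = (iy - (ny - 1) / 2.0) * self.square_size
        return np.column_stack([x, y, np.zeros_like(x)])


@dataclass
class CameraGraph:
    """Co-visibility graph over cameras with greedily selected spanning edges."""

    nodes: list[str]
    weights: dict[tuple[str, str], int]
    spanning_edges: list[tuple[str, str]]

    def neighbors(self, name: str) -> list[str]:
        out = []
        for a, b in self.spanning_edges:
            if a == name:
                out.append(b)
            elif b == name:
                out.append(a)
        return out


def validate_detections(detections: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DETECTION_COLUMNS if c not in detections.columns]
    if missing:
        raise ValueError(f"detections missing columns {missing}")
    if detections.duplicated(["camera", "frame", "corner_id"]).any():
        raise ValueError("duplicate (camera, frame, corner_id) rows in detections")
    return detections


def _frames_with_pose(detections: pd.DataFrame, min_corners: int = 4) -> pd.DataFrame:
    """Per (camera, frame) corner counts, restricted to pose-estimable frames."""
    counts = detections.groupby(["camera", "frame"]).size().reset_index(name="n")
    return counts[counts["n"] >= min_corners]


def build_camera_graph(detections: pd.DataFrame) -> CameraGraph:
    """Greedy construction of the camera connectivity graph.

    Camera pairs are visited in decreasing order of the number of frames in
    which both cameras see the board; an edge is added iff its endpoints are
    not already connected.  Calibration is possible iff the result is a
    single spanning tree.
    """
    validate_detections(detections)
    cameras = sorted(detections["camera"].unique())
    if len(cameras) < 2:
        raise CalibrationError("need at least 2 cameras to build a camera graph")

    usable = _frames_with_pose(detections)
    frames_by_cam = {c: set(g["frame"]) for c, g in usable.groupby("camera")}
    weights: dict[tuple[str, str], int] = {}
    for i, a in enumerate(cameras):
        for b in cameras[i + 1 :]:
            shared = len(frames_by_cam.get(a, set()) & frames_by_cam.get(b, set()))
            if shared > 0:
                weights[(a, b)] = shared

    # union-find
    parent = {c: c for c in cameras}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    spanning: list[tuple[str, str]] = []
    for (a, b), _w in sorted(weights.items(), key=lambda kv: (-kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            spanning.append((a, b))

    components: dict[str, list[str]] = {}
    for c in cameras:
        components.setdefault(find(c), []).append(c)
    if len(components) > 1:
        groups = sorted(sorted(g) for g in components.values())
        raise CalibrationError(
            "camera graph is disconnected; calibration impossible. "
            f"Components: {groups}"
        )
    return CameraGraph(nodes=cameras, weights=weights, spanning_edges=spanning)


def initialize_intrinsics(
    detections: pd.DataFrame,
    board: BoardGeometry,
    image_sizes: dict[str, tuple[int, int]],
    min_frames: int = 3,
) -> dict[str, float]:
    """Closed-form focal estimate per camera from board homographies.

    Distortion is initialized to zero and the principal point sits at the
    image center.  When too few usable frames exist or the geometry is
    degenerate (e.g. every view fronto-parallel), falls back to a
    field-of-view prior (focal = image width, ~53 deg horizontal FOV) with a
    warning.
    """
    validate_detections(detections)
    focals: dict[str, float] = {}
    for cam_name, group in detections.groupby("camera"):
        size = image_sizes[cam_name]
        pp = np.array([size[0] / 2.0, size[1] / 2.0])
        homographies = []
        for _frame, obs in group.groupby("frame"):
            if len(obs) < 4:
                continue
            ids = obs["corner_id"].to_numpy(int)
            board_xy = board.canonical_corners(ids)[:, :2]
            try:
                H = estimate_homography(board_xy, obs[["x", "y"]].to_numpy(float))
            except (ValueError, np.linalg.LinAlgError):
                continue
            homographies.append(H)
        if len(homographies) < min_frames:
            logger.warning(
                "camera %s: only %d usable frames for intrinsics; "
                "falling back to FOV-prior focal",
                cam_name,
                len(homographies),
            )
            focals[cam_name] = float(size[0])
            continue
        try:
            focals[cam_name] = focal_from_homographies(homographies, pp)
        except ValueError:
            logger.warning(
                "camera %s: degenerate geometry for focal initialization; "
                "falling back to FOV-prior focal",
                cam_name,
            )
            focals[cam_name] = float(size[0])
    return focals


def _board_poses(
    detections: pd.DataFrame,
    board: BoardGeometry,
    focal: float,
    principal_point: np.ndarray,
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per-frame board pose (R, t) for a single camera's detections."""
    poses = {}
    for frame, obs in detections.groupby("frame"):
        if len(obs) < 4:
            continue
        ids = obs["corner_id"].to_numpy(int)
        board_xy = board.canonical_corners(ids)[:, :2]
        try:
            H = estimate_homography(board_xy, obs[["x", "y"]].to_numpy(float))
            R, t = pose_from_homography(H, focal, principal_point)
        except (ValueError, np.linalg.LinAlgError):
            continue
        poses[int(frame)] = (R, t)
    return poses


def _geometric_median(X: np.ndarray, n_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld geometric median with component-wise median fallback."""
    med = np.median(X, axis=0)
    if len(X) <= 2:
        return med
    y = med.copy()
    for _ in range(n_iter):
        d = np.linalg.norm(X - y, axis=1)
        if np.any(d < 1e-12):
            return y
        w = 1.0 / d
        y_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _average_pose(rotations: list[np.ndarray], translations: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Robust average of rigid transforms: geometric median of sign-aligned
    quaternions (rotation-vector medians break down near 180-degree rotations,
    which opposite cameras on a ring produce) and of translations."""
    from scipy.spatial.transform import Rotation

    quats = np.array([Rotation.from_matrix(R).as_quat() for R in rotations])
    signs = np.where(quats @ quats[0] < 0, -1.0, 1.0)
    quats = quats * signs[:, None]
    q_med = _geometric_median(quats)
    q_med = q_med / np.linalg.norm(q_med)
    t_med = _geometric_median(np.asarray(translations))
    return Rotation.from_quat(q_med).as_matrix(), t_med


def initialize_extrinsics(
    graph: CameraGraph,
    detections: pd.DataFrame,
    board: BoardGeometry,
    intrinsics: dict[str, float],
    image_sizes: dict[str, tuple[int, int]],
) -> CameraRig:
    """Propagate extrinsics over the spanning tree from an identity root.

    The root camera (lexicographically first node) gets zero rotation and
    translation; each neighbor is initialized from the relative pose of the
    board observed simultaneously by the pair, averaged over shared frames
    with a geometric median in (rotation-vector, translation) space.
    """
    from scipy.spatial.transform import Rotation

    validate_detections(detections)
    pp = {c: np.array([image_sizes[c][0] / 2.0, image_sizes[c][1] / 2.0]) for c in graph.nodes}
    poses = {
        c: _board_poses(detections[detections["camera"] == c], board, intrinsics[c], pp[c])
        for c in graph.nodes
    }

    root = graph.nodes[0]
    # world-to-camera transforms, world = root camera frame
    transforms: dict[str, tuple[np.ndarray, np.ndarray]] = {root: (np.eye(3), np.zeros(3))}
    queue = [root]
    while queue:
        parent = queue.pop(0)
        for child in graph.neighbors(parent):
            if child in transforms:
                continue
            shared = sorted(set(poses[parent]) & set(poses[child]))
            rel_R, rel_t = [], []
            for f in shared:
                Rp, tp = poses[parent][f]
                Rc, tc = poses[child][f]
                # child <- parent: T_c o T_p^-1
                R_rel = Rc @ Rp.T
                rel_R.append(R_rel)
                rel_t.append(tc - R_rel @ tp)
            if not rel_R:
                raise CalibrationError(
                    f"no shared frames with estimable board pose on edge ({parent}, {child})"
                )
            R_rel, t_rel = _average_pose(rel_R, rel_t)
            Rp, tp = transforms[parent]
            transforms[child] = (R_rel @ Rp, R_rel @ tp + t_rel)
            queue.append(child)

    cams = []
    for name in graph.nodes:
        R, t = transforms[name]
        cams.append(
            CameraParameters(
                rotation=Rotation.from_matrix(R).as_rotvec(),
                translation=t,
                focal=intrinsics[name],
                image_size=image_sizes[name],
                k1=0.0,
                name=name,
            )
        )
    return CameraRig(cams)


def initialize_points3d(
    rig: CameraRig,
    detections: pd.DataFrame,
    board: BoardGeometry,
) -> pd.DataFrame:
    """Initial free 3D corner positions from per-camera board poses.

    For every frame, the board pose seen by each camera is mapped into world
    coordinates and the component-wise median over cameras is taken; canonical
    corners are then placed with that pose.  Returns a DataFrame
    ``(frame, corner_id, x, y, z)``.
    """
    from scipy.spatial.transform import Rotation

    pose_by_cam = {
        cam.name: _board_poses(
            detections[detections["camera"] == cam.name], board, cam.focal, cam.principal_point
        )
        for cam in rig
    }
    frames = sorted(detections["frame"].unique())
    records = []
    corners = board.canonical_corners()
    for f in frames:
        world_R, world_t = [], []
        for cam in rig:
            if f not in pose_by_cam[cam.name]:
                continue
            Rb, tb = pose_by_cam[cam.name][f]  # board -> camera
            Rc = cam.rotation_matrix
            tc = cam.translation
            # board -> world = (world->cam)^-1 o (board->cam)
            world_R.append(Rc.T @ Rb)
            world_t.append(Rc.T @ (tb - tc))
        if not world_R:
            continue
        Rw, tw = _average_pose(world_R, world_t)
        pts = corners @ Rw.T + tw
        for cid, p in enumerate(pts):
            records.append((f, cid, p[0], p[1], p[2]))
    return pd.DataFrame(records, columns=["frame", "corner_id", "x", "y", "z"])


def reprojection_errors(
    rig: CameraRig,
    detections: pd.DataFrame,
    points3d: pd.DataFrame,
) -> pd.Series:
    """Per-observation reprojection residual magnitudes in pixels.

    Observations whose (frame, corner_id) has no 3D point get NaN.
    """
    pts = points3d.set_index(["frame", "corner_id"])[["x", "y", "z"]]
    errors = np.full(len(detections), np.nan)
    det = detections.reset_index(drop=True)
    for cam in rig:
        mask = (det["camera"] == cam.name).to_numpy()
        if not mask.any():
            continue
        sub = det[mask]
        keys = pd.MultiIndex.from_arrays([sub["frame"], sub["corner_id"]])
        valid = keys.isin(pts.index)
        if not valid.any():
            continue
        p3 = pts.loc[keys[valid]].to_numpy(float)
        uv = project(p3, cam)
        obs = sub[["x", "y"]].to_numpy(float)[valid]
        idx = np.nonzero(mask)[0][valid]
        errors[idx] = np.linalg.norm(uv - obs, axis=1)
    return pd.Series(errors, index=det.index, name="reprojection_error")


@dataclass
class BundleSummary:
    initial_error: float
    final_error: float
    n_observations: int
    converged: bool
    message: str = ""
    history: list[dict] = field(default_factory=list)


def _pack(rig: CameraRig, points: np.ndarray) -> np.ndarray:
    return np.concatenate([c.to_vector() for c in rig] + [points.ravel()])


def _unpack(x: np.ndarray, rig: CameraRig, n_points: int) -> tuple[CameraRig, np.ndarray]:
    ncam = len(rig)
    cams = [rig[i].with_vector(x[8 * i : 8 * (i + 1)]) for i in range(ncam)]
    pts = x[8 * ncam :].reshape(n_points, 3)
    return CameraRig(cams, metadata=rig.metadata), pts


def _ba_residuals(x, rig, n_points, cam_idx, pt_idx, obs_xy):
    rig2, pts = _unpack(x, rig, n_points)
    res = np.empty((len(obs_xy), 2))
    for ci, cam in enumerate(rig2):
        m = cam_idx == ci
        if not m.any():
            continue
        uv = project(pts[pt_idx[m]], cam)
        res[m] = uv - obs_xy[m]
    res = np.nan_to_num(res, nan=0.0, posinf=1e6, neginf=-1e6)
    return res.ravel()


def _ba_sparsity(n_cams, n_points, cam_idx, pt_idx):
    m = 2 * len(cam_idx)
    n = 8 * n_cams + 3 * n_points
    A = lil_matrix((m, n), dtype=int)
    i = np.arange(len(cam_idx))
    for k in range(8):
        A[2 * i, 8 * cam_idx + k] = 1
        A[2 * i + 1, 8 * cam_idx + k] = 1
    for k in range(3):
        A[2 * i, 8 * n_cams + 3 * pt_idx + k] = 1
        A[2 * i + 1, 8 * n_cams + 3 * pt_idx + k] = 1
    return A


def bundle_adjust(
    rig: CameraRig,
    detections: pd.DataFrame,
    board: BoardGeometry,
    loss: str = "linear",
    loss_scale: float = 10.0,
    points3d: pd.DataFrame | None = None,
    max_nfev: int | None = None,
    ftol: float = 1e-10,
    verbose: int = 0,
) -> tuple[CameraRig, pd.DataFrame, BundleSummary]:
    """Jointly refine all camera parameters and free 3D corner positions.

    Sparse nonlinear least squares (Trust Region Reflective) on the stacked
    per-observation reprojection residuals, with ``loss`` in
    {'linear', 'huber', 'soft_l1'} and robust scale ``loss_scale`` in pixels.
    """
    if loss not in ("linear", "huber", "soft_l1"):
        raise ValueError(f"unknown loss {loss!r}")
    validate_detections(detections)
    if points3d is None:
        points3d = initialize_points3d(rig, detections, board)

    pts_index = pd.MultiIndex.from_frame(points3d[["frame", "corner_id"]])
    key_to_idx = {k: i for i, k in enumerate(pts_index)}
    det = detections.reset_index(drop=True)
    keys = list(zip(det["frame"].astype(int), det["corner_id"].astype(int)))
    usable = np.array([k in key_to_idx for k in keys])
    det = det[usable].reset_index(drop=True)
    cam_names = rig.names
    cam_idx = det["camera"].map({n: i for i, n in enumerate(cam_names)}).to_numpy(int)
    pt_idx = np.array([key_to_idx[k] for k, u in zip(keys, usable) if u])
    obs_xy = det[["x", "y"]].to_numpy(float)

    n_free = 8 * len(rig) + 3 * len(points3d)
    if 2 * len(det) < n_free:
        raise CalibrationError(
            f"too few observations ({len(det)}) for {n_free} free parameters"
        )

    pts0 = points3d[["x", "y", "z"]].to_numpy(float)
    x0 = _pack(rig, pts0)
    r0 = _ba_residuals(x0, rig, len(pts0), cam_idx, pt_idx, obs_xy).reshape(-1, 2)
    initial_error = float(np.mean(np.linalg.norm(r0, axis=1)))

    A = _ba_sparsity(len(rig), len(pts0), cam_idx, pt_idx)
    result = least_squares(
        _ba_residuals,
        x0,
        args=(rig, len(pts0), cam_idx, pt_idx, obs_xy),
        jac_sparsity=A,
        method="trf",
        loss=loss,
        f_scale=loss_scale,
        x_scale="jac",
        ftol=ftol,
        verbose=verbose,
        max_nfev=max_nfev,
    )
    rig2, pts2 = _unpack(result.x, rig, len(pts0))
    rf = _ba_residuals(result.x, rig, len(pts0), cam_idx, pt_idx, obs_xy).reshape(-1, 2)
    final_error = float(np.mean(np.linalg.norm(rf, axis=1)))
    out_points = points3d.copy()
    out_points[["x", "y", "z"]] = pts2
    summary = BundleSummary(
        initial_error=initial_error,
        final_error=final_error,
        n_observations=len(det),
        converged=result.status > 0,
        message=result.message,
    )
    return rig2, out_points, summary


def iterative_bundle_adjust(
    rig: CameraRig,
    detections: pd.DataFrame,
    board: BoardGeometry,
    n_iter: int = 12,
    mu_start: float = 15.0,
    mu_end: float = 1.0,
    max_frames: int = 100,
    seed: int | np.random.SeedSequence | None = 0,
    max_nfev: int | None = 30,
    verbose: int = 0,
) -> tuple[CameraRig, pd.DataFrame, BundleSummary]:
    """Bundle adjustment with an exponentially decaying inlier threshold.

    At iteration ``i`` the pixel threshold is
    ``mu_i = mu_start * (mu_end / mu_start) ** (i / (n_iter - 1))`` and only
    observations whose current reprojection error falls below ``mu_i``
    (within a random subsample of at most ``max_frames`` frames) enter the
    adjustment.  Outliers are thereby excluded without tuning a robust-loss
    scale.  The returned summary reports errors over all observations.
    """
    validate_detections(detections)
    rng = np.random.default_rng(seed)
    det = detections.reset_index(drop=True)
    points3d = initialize_points3d(rig, det, board)
    n_params = 8 * len(rig)
    min_obs = MIN_OBS_PER_PARAM * n_params

    errs0 = reprojection_errors(rig, det, points3d)
    initial_error = float(np.nanmean(errs0))
    history = []

    if n_iter < 2:
        thresholds = np.array([mu_end], dtype=float)[:n_iter]
    else:
        i = np.arange(n_iter)
        thresholds = mu_start * (mu_end / mu_start) ** (i / (n_iter - 1))

    for it, mu in enumerate(thresholds):
        errs = reprojection_errors(rig, det, points3d)
        frames = np.sort(det["frame"].unique())
        if len(frames) > max_frames:
            frames = np.sort(rng.choice(frames, size=max_frames, replace=False))
        in_frames = det["frame"].isin(frames)
        selected = in_frames & (errs < mu)
        if selected.sum() < min_obs:
            logger.info(
                "iterative BA iter %d: only %d observations below %.2f px; keeping iterate",
                it,
                int(selected.sum()),
                mu,
            )
            history.append({"iteration": it, "threshold": float(mu), "n_selected": int(selected.sum()), "skipped": True})
            continue
        sub_det = det[selected]
        sub_pts_keys = sub_det[["frame", "corner_id"]].drop_duplicates()
        sub_pts = points3d.merge(sub_pts_keys, on=["frame", "corner_id"])
        try:
            rig, new_pts, summ = bundle_adjust(
                rig,
                sub_det,
                board,
                loss="linear",
                points3d=sub_pts,
                max_nfev=max_nfev,
                ftol=1e-8,
                verbose=verbose,
            )
        except CalibrationError:
            history.append({"iteration": it, "threshold": float(mu), "n_selected": int(selected.sum()), "skipped": True})
            continue
        # merge refined point subset back, then re-derive the rest
        points3d = points3d.set_index(["frame", "corner_id"])
        new_pts = new_pts.set_index(["frame", "corner_id"])
        points3d.loc[new_pts.index, ["x", "y", "z"]] = new_pts[["x", "y", "z"]]
        points3d = points3d.reset_index()
        history.append(
            {
                "iteration": it,
                "threshold": float(mu),
                "n_selected": int(selected.sum()),
                "error": summ.final_error,
                "skipped": False,
            }
        )

    # final re-triangulation of all points with the refined rig, then report
    points3d = _retriangulate_points(rig, det, points3d)
    errs = reprojection_errors(rig, det, points3d)
    final_error = float(np.nanmean(errs))
    summary = BundleSummary(
        initial_error=initial_error,
        final_error=final_error,
        n_observations=int(errs.notna().sum()),
        converged=True,
        history=history,
    )
    return rig, points3d, summary


def _retriangulate_points(
    rig: CameraRig,
    detections: pd.DataFrame,
    points3d: pd.DataFrame,
    ransac_above: float = 5.0,
) -> pd.DataFrame:
    """Re-triangulate every (frame, corner) seen by >=2 cameras with the
    refined rig: linear SVD first, falling back to the exhaustive-pair
    consensus search when the linear solution reprojects worse than
    ``ransac_above`` pixels (i.e. an outlier view is present).  Points seen
    by fewer than 2 cameras keep their current estimate."""
    from .triangulation import triangulate_linear, triangulate_ransac

    out = points3d.copy().set_index(["frame", "corner_id"])
    cam_order = {n: i for i, n in enumerate(rig.names)}
    cam_idx = detections["camera"].map(cam_order).to_numpy()
    xy = detections[["x", "y"]].to_numpy(float)
    keys = detections[["frame", "corner_id"]].to_numpy(int)
    order = np.lexsort((keys[:, 1], keys[:, 0]))
    boundaries = np.flatnonzero(
        np.any(np.diff(keys[order], axis=0) != 0, axis=1)
    ) + 1
    for grp in np.split(order, boundaries):
        if len(grp) < 2:
            continue
        key = tuple(keys[grp[0]])
        obs = np.full((len(rig), 2), np.nan)
        obs[cam_idx[grp]] = xy[grp]
        p, err = triangulate_linear(obs, rig)
        if np.isfinite(err) and err > ransac_above and len(grp) > 2:
            p2, err2 = triangulate_ransac(obs, rig)
            if np.isfinite(err2) and err2 < err:
                p = p2
        if np.isfinite(p).all() and key in out.index:
            out.loc[key, ["x", "y", "z"]] = p
    return out.reset_index()


def fix_rig_scale(
    rig: CameraRig,
    points3d: pd.DataFrame,
    board: BoardGeometry,
) -> tuple[CameraRig, pd.DataFrame, float]:
    """Anchor the metric scale of a calibrated rig to the board geometry.

    Multi-camera calibration determines the rig only up to a global scale;
    the board's known square size fixes it.  The median ratio of canonical to
    reconstructed corner spacing (horizontally adjacent corner pairs, all
    frames) rescales camera translations and 3D points.
    """
    nx = board.squares_x - 1
    ratios = []
    for _frame, grp in points3d.groupby("frame"):
        ids = grp["corner_id"].to_numpy(int)
        pts = grp[["x", "y", "z"]].to_numpy(float)
        pos = {i: p for i, p in zip(ids, pts)}
        for cid in ids:
            right = cid + 1
            if right in pos and (cid % nx) < nx - 1:
                d = np.linalg.norm(pos[right] - pos[cid])
                if d > 0:
                    ratios.append(board.square_size / d)
    if not ratios:
        return rig, points3d, 1.0
    s = float(np.median(ratios))
    cams = [
        CameraParameters(
            rotation=c.rotation,
            translation=c.translation * s,
            focal=c.focal,
            image_size=c.image_size,
            k1=c.k1,
            name=c.name,
        )
        for c in rig
    ]
    pts = points3d.copy()
    pts[["x", "y", "z"]] *= s
    return CameraRig(cams, metadata=rig.metadata), pts, s


def calibrate_rig(
    detections: pd.DataFrame,
    board: BoardGeometry,
    image_sizes: dict[str, tuple[int, int]],
    n_iter: int = 12,
    mu_start: float = 15.0,
    mu_end: float = 1.0,
    seed: int | np.random.SeedSequence | None = 0,
    anchor_scale: bool = True,
    verbose: int = 0,
) -> tuple[CameraRig, pd.DataFrame, BundleSummary]:
    """Full calibration: graph init + intrinsics + iterative bundle adjustment."""
    graph = build_camera_graph(detections)
    focals = initialize_intrinsics(detections, board, image_sizes)
    rig = initialize_extrinsics(graph, detections, board, focals, image_sizes)
    rig, points3d, summary = iterative_bundle_adjust(
        rig, detections, board, n_iter=n_iter, mu_start=mu_start, mu_end=mu_end,
        seed=seed, verbose=verbose,
    )
    if anchor_scale:
        rig, points3d, _s = fix_rig_scale(rig, points3d, board)
    return rig, points3d, summary
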