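"""Tabular interchange formats for keypoints, trajectories, and angles.

Everything on disk is a flat table — CSV by default, HDF5 (pandas/pytables)
when the filename ends in ``.h5`` — so intermediate results stay inspectable
with ordinary tools:

- 2D candidates: ``(camera, frame, joint, rank, x, y, score)``
- filtered 2D series: the same without ``rank``
- 3D trajectories: ``(frame, joint, x, y, z, reprojection_error, n_cams)``
- angles: ``(frame, angle_name, kind, value_deg)``

The in-memory convention is dense NaN-padded numpy arrays (see
:mod:`ringpose.filters2d`); converters here go both ways.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import AngleSeries
from .triangulation import Trajectory3D


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        return pd.read_hdf(path, key="table")
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in (".h5", ".hdf5"):
        df.to_hdf(path, key="table", mode="w")
    else:
        df.to_csv(path, index=False)


def candidates_to_table(
    positions: np.ndarray, scores: np.ndarray, cameras: list[str], joints: list[str]
) -> pd.DataFrame:
    """(n_cams, T, J, n_cand, 2) + scores -> long candidate table."""
    C, T, J, N, _ = positions.shape
    recs = []
    for ci in range(C):
        for t in range(T):
            for j in range(J):
                for r in range(N):
                    if np.isfinite(scores[ci, t, j, r]):
                        x, y = positions[ci, t, j, r]
                        recs.append((cameras[ci], t, joints[j], r, x, y, scores[ci, t, j, r]))
    return pd.DataFrame(recs, columns=["camera", "frame", "joint", "rank", "x", "y", "score"])


def table_to_candidates(
    df: pd.DataFrame, cameras: list[str] | None = None, joints: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Long candidate table -> dense arrays (candidates sorted by rank)."""
    if cameras is None:
        cameras = sorted(df["camera"].unique())
    if joints is None:
        joints = sorted(df["joint"].unique())
    has_rank = "rank" in df.columns
    n_cand = int(df["rank"].max()) + 1 if has_rank else 1
    T = int(df["frame"].max()) + 1
    cam_idx = {c: i for i, c in enumerate(cameras)}
    joint_idx = {j: i for i, j in enumerate(joints)}
    pos = np.full((len(cameras), T, len(joints), n_cand, 2), np.nan)
    scores = np.full((len(cameras), T, len(joints), n_cand), np.nan)
    for row in df.itertuples(index=False):
        ci = cam_idx[row.camera]
        ji = joint_idx[row.joint]
        r = int(row.rank) if has_rank else 0
        pos[ci, int(row.frame), ji, r] = (row.x, row.y)
        scores[ci, int(row.frame), ji, r] = getattr(row, "score", 1.0)
    return pos, scores, cameras, joints


def series_to_table(
    positions: np.ndarray, scores: np.ndarray, cameras: list[str], joints: list[str]
) -> pd.DataFrame:
    """(n_cams, T, J, 2) + (n_cams, T, J) scores -> long series table."""
    C, T, J, _ = positions.shape
    recs = []
    for ci in range(C):
        for t in range(T):
            for j in range(J):
                if np.isfinite(positions[ci, t, j]).all():
                    x, y = positions[ci, t, j]
                    recs.append((cameras[ci], t, joints[j], x, y, scores[ci, t, j]))
    return pd.DataFrame(recs, columns=["camera", "frame", "joint", "x", "y", "score"])


def table_to_series(
    df: pd.DataFrame, cameras: list[str] | None = None, joints: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    if cameras is None:
        cameras = sorted(df["camera"].unique())
    if joints is None:
        joints = sorted(df["joint"].unique())
    T = int(df["frame"].max()) + 1
    cam_idx = {c: i for i, c in enumerate(cameras)}
    joint_idx = {j: i for i, j in enumerate(joints)}
    pos = np.full((len(cameras), T, len(joints), 2), np.nan)
    scores = np.full((len(cameras), T, len(joints)), np.nan)
    for row in df.itertuples(index=False):
        ci = cam_idx[row.camera]
        ji = joint_idx[row.joint]
        pos[ci, int(row.frame), ji] = (row.x, row.y)
        scores[ci, int(row.frame), ji] = getattr(row, "score", 1.0)
    return pos, scores, cameras, joints


def trajectory_to_table(traj: Trajectory3D) -> pd.DataFrame:
    T, J, _ = traj.positions.shape
    err = traj.reprojection_error if traj.reprojection_error is not None else np.full((T, J), np.nan)
    ncam = traj.n_cams if traj.n_cams is not None else np.zeros((T, J), int)
    recs = []
    for t in range(T):
        for j in range(J):
            x, y, z = traj.positions[t, j]
            recs.append((t, traj.joints[j], x, y, z, err[t, j], int(ncam[t, j])))
    return pd.DataFrame(
        recs, columns=["frame", "joint", "x", "y", "z", "reprojection_error", "n_cams"]
    )


def table_to_trajectory(df: pd.DataFrame, frame_rate: float = 1.0) -> Trajectory3D:
    joints = list(dict.fromkeys(df["joint"]))
    T = int(df["frame"].max()) + 1
    joint_idx = {j: i for i, j in enumerate(joints)}
    pos = np.full((T, len(joints), 3), np.nan)
    err = np.full((T, len(joints)), np.nan)
    ncam = np.zeros((T, len(joints)), int)
    for row in df.itertuples(index=False):
        ji = joint_idx[row.joint]
        pos[int(row.frame), ji] = (row.x, row.y, row.z)
        err[int(row.frame), ji] = getattr(row, "reprojection_error", np.nan)
        ncam[int(row.frame), ji] = int(getattr(row, "n_cams", 0))
    return Trajectory3D(pos, joints, frame_rate, err, ncam)


def angles_to_table(angles: AngleSeries) -> pd.DataFrame:
    T, n = angles.values.shape
    recs = []
    for t in range(T):
        for i in range(n):
            recs.append((t, angles.names[i], angles.kinds[i], angles.values[t, i]))
    return pd.DataFrame(recs, columns=["frame", "angle_name", "kind", "value_deg"])


def table_to_angles(df: pd.DataFrame, frame_rate: float = 1.0) -> AngleSeries:
    names = list(dict.fromkeys(df["angle_name"]))
    kinds = [df[df["angle_name"] == n]["kind"].iloc[0] for n in names]
    T = int(df["frame"].max()) + 1
    vals = np.full((T, len(names)), np.nan)
    name_idx = {n: i for i, n in enumerate(names)}
    for row in df.itertuples(index=False):
        vals[int(row.frame), name_idx[row.angle_name]] = row.value_deg
    return AngleSeries(vals, names, kinds, frame_rate)
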