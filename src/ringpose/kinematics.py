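"""Joint angles, step phase, and embedding features from 3D trajectories.

Flexion at a joint is the angle between the unit vectors to its two
neighboring joints.  Rotation (twist about the limb's long axis) and
abduction (out-of-plane deviation) are obtained by solving a small inverse
kinematics problem: each joint along a kinematic chain gets a coordinate
frame (z along the distal limb segment, x toward the body orthogonalized
against z, y = z cross x), and the relative rotation between consecutive
frames is decomposed as intrinsic Euler angles in {z, y, x} order —
(rotation, flexion, abduction).  From 3D joint positions alone, the rotation
of one joint is indistinguishable from the abduction of the next, so the
decomposition assumes that only the most proximal joint abducts and the most
distal joint does not rotate — a good approximation for insect and human
limbs.

The module also builds the standardized windowed feature matrices used for
behavioral embeddings (angles + derivatives over sliding chunks) and
estimates step-cycle phase from the analytic signal of a band-passed joint
angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, hilbert
from scipy.spatial.transform import Rotation

from ._geometry import orthogonalize
from .triangulation import Trajectory3D

#: flexion this close (degrees) to 0 or 180 makes rotation/abduction degenerate
GIMBAL_TOL_DEG = 0.1


@dataclass
class AngleSeries:
    """Frames x named angles, in degrees.

    ``kinds`` tags each angle as flexion ([0, 180] deg), rotation, or
    abduction (both in [-180, 180) deg); missing values are NaN.
    """

    values: np.ndarray  # (T, n_angles) degrees
    names: list[str]
    kinds: list[str]
    frame_rate: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (frames, n_angles) matching names")
        if len(self.kinds) != len(self.names):
            raise ValueError("kinds must match names")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def flexion_angle(p_i: np.ndarray, p_j: np.ndarray, p_k: np.ndarray) -> np.ndarray:
    """Angle (degrees) at ``p_j`` between unit vectors toward ``p_i`` and ``p_k``.

    Vectorized over leading axes; zero-length segments give NaN.  The dot
    product of the unit vectors is clamped to [-1, 1] before arccos.
    """
    p_i, p_j, p_k = (np.asarray(p, dtype=float) for p in (p_i, p_j, p_k))
    a = p_i - p_j
    b = p_k - p_j
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(a * b, axis=-1) / (na * nb)
        cosang = np.where((na > 0) & (nb > 0), cosang, np.nan)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _euler_zyx_chain(R: np.ndarray) -> tuple[float, float, float]:
    """Intrinsic {z, y, x} Euler angles with the middle angle in [0, 180] deg.

    Of the two exact Euler decompositions, returns the branch with
    |x-angle| <= 90 deg, which is the physically meaningful one under the
    proximal-abduction convention (middle joints have ~zero abduction).
    """
    a, b, c = Rotation.from_matrix(R).as_euler("ZYX", degrees=True)

    def wrap(x):
        return (x + 180.0) % 360.0 - 180.0

    cand1 = (a, b, c)
    cand2 = (wrap(a + 180.0), 180.0 - b, wrap(c + 180.0))
    chosen = cand1 if abs(cand1[2]) <= abs(cand2[2]) else cand2
    if not (-1e-9 <= chosen[1] <= 180.0 + 1e-9):
        chosen = cand2 if chosen is cand1 else cand1
    return chosen


def euler_rotation_zyx(rotation_deg: float, flexion_deg: float, abduction_deg: float) -> np.ndarray:
    """Rotation matrix of one chain link from its named angles.

    Inverse of the decomposition in :func:`chain_angles`: intrinsic rotations
    about z (rotation), y (by 180 deg - flexion), x (abduction).
    """
    return Rotation.from_euler(
        "ZYX", [rotation_deg, 180.0 - flexion_deg, abduction_deg], degrees=True
    ).as_matrix()


def _chain_frames(points: np.ndarray, body_x: np.ndarray) -> np.ndarray:
    """Per-joint coordinate frames along one chain at one frame.

    ``points`` is (K, 3); returns (K-1, 3, 3) rotation matrices whose columns
    are the x, y, z axes.  z points along the distal segment; x is the
    proximal direction (toward the body) orthogonalized against z; the first
    joint, lacking a proximal segment, takes its x reference from the body
    frame.  NaN matrices mark degenerate (parallel-segment) joints.
    """
    K = len(points)
    frames = np.full((K - 1, 3, 3), np.nan)
    for j in range(K - 1):
        seg = points[j + 1] - points[j]
        n = np.linalg.norm(seg)
        if not np.isfinite(n) or n < 1e-12:
            continue
        z = seg / n
        ref = body_x if j == 0 else points[j - 1] - points[j]
        x = orthogonalize(ref, z)
        if not np.isfinite(x).all():
            continue
        y = np.cross(z, x)
        frames[j] = np.column_stack([x, y, z])
    return frames


def chain_angles(
    traj: Trajectory3D,
    chain: list[str],
    body_frame: np.ndarray | None = None,
) -> AngleSeries:
    """Rotation / flexion / abduction angles along one kinematic chain.

    Parameters
    ----------
    traj : Trajectory3D
    chain : ordered joint names from the body outward, length >= 3.
    body_frame : (3, 3) or (T, 3, 3) array, optional
        Rotation whose columns are the body's x (anterior), y, z axes in
        world coordinates; it supplies the twist reference of the first
        segment.  Defaults to the world frame.

    Angles are reported per interior joint of the chain.  Abduction is only
    reported for the first interior joint and rotation is not reported for
    the last one (they are unobservable from positions elsewhere).  Frames
    where consecutive segments are parallel, or where flexion approaches
    0/180 deg (gimbal lock), get NaN rotation/abduction.
    """
    if len(chain) < 3:
        raise ValueError("chain needs at least 3 joints")
    idx = [traj.joints.index(j) for j in chain]
    pts = traj.positions[:, idx, :]  # (T, K, 3)
    T, K, _ = pts.shape
    if body_frame is None:
        body_frame = np.eye(3)
    body_frame = np.asarray(body_frame, dtype=float)
    if body_frame.ndim == 2:
        body_frame = np.broadcast_to(body_frame, (T, 3, 3))

    n_triples = K - 2
    names: list[str] = []
    kinds: list[str] = []
    for i in range(n_triples):
        joint = chain[i + 1]
        if i < n_triples - 1:
            names.append(f"{joint}_rotation")
            kinds.append("rotation")
        names.append(f"{joint}_flexion")
        kinds.append("flexion")
        if i == 0:
            names.append(f"{joint}_abduction")
            kinds.append("abduction")

    values = np.full((T, len(names)), np.nan)
    for t in range(T):
        frames = _chain_frames(pts[t], body_frame[t][:, 0])
        col = 0
        for i in range(n_triples):
            Ra, Rb = frames[i], frames[i + 1]
            if np.isfinite(Ra).all() and np.isfinite(Rb).all():
                rot, ey, abd = _euler_zyx_chain(Ra.T @ Rb)
                flex = 180.0 - ey
                gimbal = min(flex, 180.0 - flex) < GIMBAL_TOL_DEG
            else:
                rot = flex = abd = np.nan
                gimbal = True
            if i < n_triples - 1:
                values[t, col] = np.nan if gimbal else rot
                col += 1
            values[t, col] = flex
            col += 1
            if i == 0:
                values[t, col] = np.nan if gimbal else abd
                col += 1
    return AngleSeries(values, names, kinds, traj.frame_rate)


def body_frame_from_keypoints(
    traj: Trajectory3D,
    origin: str,
    anterior: str,
    dorsal: str,
) -> np.ndarray:
    """Per-frame body frame from three named reference keypoints.

    x points from ``origin`` toward ``anterior``; z is the direction toward
    ``dorsal`` orthogonalized against x (Gram-Schmidt); y = z cross x.
    Returns (T, 3, 3) rotation matrices whose columns are the axes; frames
    with missing or degenerate references are NaN.
    """
    io_ = traj.joints.index(origin)
    ia = traj.joints.index(anterior)
    id_ = traj.joints.index(dorsal)
    p0 = traj.positions[:, io_]
    ant = traj.positions[:, ia] - p0
    dor = traj.positions[:, id_] - p0
    nx = np.linalg.norm(ant, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(nx > 1e-12, ant / nx, np.nan)
    z = orthogonalize(dor, x)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=-1)


def forward_kinematics(
    base: np.ndarray,
    body_frame: np.ndarray,
    lengths: np.ndarray,
    rotation: np.ndarray,
    flexion: np.ndarray,
    abduction: np.ndarray,
) -> np.ndarray:
    """Chain joint positions from angles (inverse of :func:`chain_angles`).

    Parameters
    ----------
    base : (T, 3) or (3,) base joint position.
    body_frame : (3, 3) or (T, 3, 3) rotation; the first segment leaves the
        base along the body z axis.
    lengths : (K-1,) segment lengths.
    rotation, flexion, abduction : (T, K-2) angle arrays in degrees.
        Consistency with position-only observation requires abduction = 0
        beyond the first link and rotation = 0 on the last link.

    Returns (T, K, 3) positions.
    """
    rotation = np.atleast_2d(np.asarray(rotation, dtype=float))
    flexion = np.atleast_2d(np.asarray(flexion, dtype=float))
    abduction = np.atleast_2d(np.asarray(abduction, dtype=float))
    T, n_triples = flexion.shape
    lengths = np.asarray(lengths, dtype=float)
    K = n_triples + 2
    if len(lengths) != K - 1:
        raise ValueError("need K-1 segment lengths for K joints")
    base = np.broadcast_to(np.asarray(base, dtype=float), (T, 3))
    body_frame = np.asarray(body_frame, dtype=float)
    if body_frame.ndim == 2:
        body_frame = np.broadcast_to(body_frame, (T, 3, 3))

    pts = np.zeros((T, K, 3))
    pts[:, 0] = base
    for t in range(T):
        R = body_frame[t]
        pts[t, 1] = pts[t, 0] + lengths[0] * R[:, 2]
        for i in range(n_triples):
            R = R @ euler_rotation_zyx(rotation[t, i], flexion[t, i], abduction[t, i])
            pts[t, i + 2] = pts[t, i + 1] + lengths[i + 1] * R[:, 2]
    return pts


def angle_derivatives(angles: AngleSeries) -> np.ndarray:
    """Forward-difference angular velocity in degrees/s, (T, n_angles).

    Rotation/abduction angles are circular: the per-frame step is wrapped to
    [-180, 180) before scaling, so a 359 deg -> 1 deg transition reads as
    +2 deg/frame.  The last frame is NaN; missing inputs propagate.
    """
    vals = angles.values
    d = np.diff(vals, axis=0)
    for i, kind in enumerate(angles.kinds):
        if kind in ("rotation", "abduction"):
            d[:, i] = (d[:, i] + 180.0) % 360.0 - 180.0
    out = np.full_like(vals, np.nan)
    out[:-1] = d * angles.frame_rate
    return out


def build_feature_vectors(
    angles: AngleSeries,
    window: int = 32,
    stride: int = 8,
    standardize: bool = True,
) -> np.ndarray:
    """Sliding-window feature matrix of angles and their derivatives.

    Each row concatenates ``window`` consecutive samples of every angle and
    of its derivative (the trailing derivative sample is held constant so a
    full window exists), giving rows of length
    ``window * n_angles * 2`` advancing by ``stride`` frames; row count is
    ``floor((T - window) / stride) + 1``.  Columns are standardized over
    rows; zero-variance columns are centered only, with a warning.
    """
    T, n_angles = angles.values.shape
    if window > T:
        return np.zeros((0, window * n_angles * 2))
    deriv = angle_derivatives(angles)
    deriv[-1] = deriv[-2] if T > 1 else 0.0
    n_rows = (T - window) // stride + 1
    rows = np.empty((n_rows, window * n_angles * 2))
    for r in range(n_rows):
        s = r * stride
        chunk = np.concatenate(
            [angles.values[s : s + window].T.ravel(), deriv[s : s + window].T.ravel()]
        )
        rows[r] = chunk
    if standardize and n_rows > 1:
        mean = np.nanmean(rows, axis=0)
        std = np.nanstd(rows, axis=0)
        zero = std < 1e-12
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} zero-variance feature columns left unscaled",
                RuntimeWarning,
            )
        std = np.where(zero, 1.0, std)
        rows = (rows - mean) / std
    return rows


def estimate_phase(
    angle: np.ndarray,
    frame_rate: float,
    band: tuple[float, float] = (3.0, 60.0),
) -> np.ndarray:
    """Instantaneous step-cycle phase of a periodic joint angle.

    The angle is band-passed with a zero-phase first-order Butterworth
    filter over ``band`` Hz and the phase of the analytic (Hilbert) signal
    is returned, wrapped to [-pi, pi).  Constant signals give NaN.
    """
    angle = np.asarray(angle, dtype=float)
    if frame_rate <= 2 * band[1]:
        raise ValueError("frame_rate must exceed twice the band's upper edge")
    if np.nanstd(angle) < 1e-12:
        return np.full_like(angle, np.nan)
    filled = np.asarray(
        np.where(np.isfinite(angle), angle, np.nanmean(angle)), dtype=float
    )
    b, a = butter(1, band, btype="bandpass", fs=frame_rate)
    filtered = filtfilt(b, a, filled)
    phase = np.angle(hilbert(filtered))
    phase = np.where(phase >= np.pi, phase - 2 * np.pi, phase)
    out = np.where(np.isfinite(angle), phase, np.nan)
    return out
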