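"""Pinhole camera model with a single radial distortion coefficient.

Each camera is described by 8 free parameters: a rotation (axis-angle,
3 parameters), a translation (3), a focal length shared between the x and y
axes (1), and the first radial distortion coefficient ``k1`` (1).  The
principal point is fixed at the image center and skew is zero — a deliberately
reduced intrinsics model that calibrates robustly from hand-held board videos.

The projection of a world point ``p`` through camera ``c`` composes the
extrinsics (rotation + translation), the perspective divide, radial distortion
in normalized camera coordinates, and finally the focal/principal-point
scaling into pixels.  Points at or behind the camera plane are reported as
missing (NaN) rather than wrapped through the projection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

#: z (camera frame) below this is treated as "behind the camera"
BEHIND_CAMERA_EPS = 1e-9


@dataclass
class CameraParameters:
    """The 8 free parameters of one camera plus its fixed principal point.

    Parameters
    ----------
    rotation : (3,) array
        World-to-camera rotation as an axis-angle (Rodrigues) vector, radians.
    translation : (3,) array
        World-to-camera translation, world units: ``p_cam = R p_world + t``.
    focal : float
        Focal length in pixels (shared by x and y).
    image_size : (int, int)
        Image width and height in pixels.  The principal point is fixed at
        ``(width / 2, height / 2)``.
    k1 : float
        First radial distortion coefficient (dimensionless, applied in
        normalized camera coordinates).
    name : str
        Camera identifier.
    """

    rotation: np.ndarray
    translation: np.ndarray
    focal: float
    image_size: tuple[int, int]
    k1: float = 0.0
    name: str = "cam"

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.focal = float(self.focal)
        self.k1 = float(self.k1)
        self.image_size = (int(self.image_size[0]), int(self.image_size[1]))
        if not np.isfinite(self.rotation).all() or not np.isfinite(self.translation).all():
            raise ValueError(f"camera {self.name!r}: non-finite extrinsics")
        if not np.isfinite(self.focal) or self.focal <= 0:
            raise ValueError(f"camera {self.name!r}: focal must be positive, got {self.focal}")
        if not np.isfinite(self.k1):
            raise ValueError(f"camera {self.name!r}: non-finite k1")

    @property
    def principal_point(self) -> np.ndarray:
        """Principal point in pixels, fixed at the image center."""
        return np.array([self.image_size[0] / 2.0, self.image_size[1] / 2.0])

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(self.rotation).as_matrix()

    @property
    def camera_center(self) -> np.ndarray:
        """Position of the camera's optical center in world coordinates."""
        R = self.rotation_matrix
        return -R.T @ self.translation

    # -- parameter vector interface used by the bundle adjuster -------------

    def to_vector(self) -> np.ndarray:
        """Pack the 8 free parameters as (rotvec, tvec, focal, k1)."""
        return np.concatenate(
            [self.rotation, self.translation, [self.focal], [self.k1]]
        )

    def with_vector(self, vec: np.ndarray) -> "CameraParameters":
        vec = np.asarray(vec, dtype=float).reshape(8)
        return replace(
            self,
            rotation=vec[:3].copy(),
            translation=vec[3:6].copy(),
            focal=float(vec[6]),
            k1=float(vec[7]),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "size": list(self.image_size),
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "focal": self.focal,
            "principal_point": self.principal_point.tolist(),
            "k1": self.k1,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CameraParameters":
        return cls(
            rotation=np.asarray(d["rotation"], dtype=float),
            translation=np.asarray(d["translation"], dtype=float),
            focal=float(d["focal"]),
            image_size=tuple(d["size"]),
            k1=float(d.get("k1", 0.0)),
            name=str(d.get("name", "cam")),
        )


def distort(normalized: np.ndarray, k1: float) -> np.ndarray:
    """Apply one-coefficient radial distortion in normalized coordinates.

    ``x' = x (1 + k1 r^2)`` with ``r^2 = x^2 + y^2``, likewise for y.
    """
    pts = np.asarray(normalized, dtype=float)
    r2 = np.sum(pts**2, axis=-1, keepdims=True)
    return pts * (1.0 + k1 * r2)


def undistort(distorted: np.ndarray, k1: float, max_iter: int = 20, tol: float = 1e-12) -> np.ndarray:
    """Invert :func:`distort` by fixed-point iteration.

    Starting from the distorted point, repeatedly divide by the distortion
    factor evaluated at the current estimate.  Converges for moderate
    ``|k1| r^2``; points that fail to converge are returned as NaN with a
    warning.
    """
    pts = np.asarray(distorted, dtype=float)
    if k1 == 0.0:
        return pts.copy()
    x = pts.copy()
    for _ in range(max_iter):
        r2 = np.sum(x**2, axis=-1, keepdims=True)
        x_new = pts / (1.0 + k1 * r2)
        delta = np.max(np.abs(x_new - x)) if x.size else 0.0
        x = x_new
        if delta < tol:
            return x
    # check convergence by forward mapping
    residual = np.abs(distort(x, k1) - pts)
    bad = np.any(residual > 1e-8, axis=-1)
    if np.any(bad):
        warnings.warn(
            f"undistort: fixed-point iteration failed for {int(np.sum(bad))} point(s); "
            "flagged missing",
            RuntimeWarning,
        )
        x = x.copy()
        x[bad] = np.nan
    return x


def project(points: np.ndarray, cam: CameraParameters) -> np.ndarray:
    """Project world points into pixel coordinates of one camera.

    Parameters
    ----------
    points : (..., 3) array
        3D points in world coordinates.
    cam : CameraParameters

    Returns
    -------
    (..., 2) array of pixel coordinates; points at or behind the camera
    plane come back as NaN.
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    pts = np.atleast_2d(pts)
    R = cam.rotation_matrix
    p_cam = pts @ R.T + cam.translation
    z = p_cam[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = p_cam[..., :2] / z[..., None]
    normalized = distort(normalized, cam.k1)
    uv = normalized * cam.focal + cam.principal_point
    uv = np.where((z > BEHIND_CAMERA_EPS)[..., None], uv, np.nan)
    return uv[0] if squeeze else uv


def pixel_to_normalized(uv: np.ndarray, cam: CameraParameters) -> np.ndarray:
    """Map pixel coordinates to undistorted normalized camera coordinates."""
    uv = np.asarray(uv, dtype=float)
    normalized = (uv - cam.principal_point) / cam.focal
    return undistort(normalized, cam.k1)


class CameraRig:
    """An ordered collection of cameras with JSON (de)serialization."""

    def __init__(self, cameras: Iterable[CameraParameters], metadata: dict | None = None):
        self.cameras: list[CameraParameters] = list(cameras)
        names = [c.name for c in self.cameras]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate camera names: {names}")
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.cameras)

    def __iter__(self):
        return iter(self.cameras)

    def __getitem__(self, key) -> CameraParameters:
        if isinstance(key, str):
            for c in self.cameras:
                if c.name == key:
                    return c
            raise KeyError(key)
        return self.cameras[key]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.cameras]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (..., 3) points through every camera -> (n_cams, ..., 2)."""
        return np.stack([project(points, c) for c in self.cameras])

    def replace_camera(self, name: str, cam: CameraParameters) -> None:
        for i, c in enumerate(self.cameras):
            if c.name == name:
                self.cameras[i] = cam
                return
        raise KeyError(name)

    def save(self, path: str | Path) -> None:
        """Write the calibration file (JSON; floats round-trip bit-exactly)."""
        payload = {
            "metadata": {"units": "world", "format": "ringpose-calibration-v1", **self.metadata},
            "cameras": [c.to_dict() for c in self.cameras],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CameraRig":
        payload = json.loads(Path(path).read_text())
        cams = [CameraParameters.from_dict(d) for d in payload["cameras"]]
        return cls(cams, metadata=payload.get("metadata", {}))


def look_at_rotation(camera_center: np.ndarray, target: np.ndarray, up: Sequence[float] = (0, 0, 1)) -> np.ndarray:
    """World-to-camera rotation matrix for a camera at ``camera_center``
    looking at ``target``, with image y roughly anti-parallel to ``up``."""
    camera_center = np.asarray(camera_center, dtype=float)
    target = np.asarray(target, dtype=float)
    forward = target - camera_center
    forward = forward / np.linalg.norm(forward)
    up = np.asarray(up, dtype=float)
    right = np.cross(forward, up)
    nrm = np.linalg.norm(right)
    if nrm < 1e-12:  # looking straight along up: pick an arbitrary right
        right = np.cross(forward, [1.0, 0.0, 0.0])
        nrm = np.linalg.norm(right)
    right = right / nrm
    down = np.cross(forward, right)
    # rows of R are the camera axes expressed in world coordinates
    return np.stack([right, down, forward])
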