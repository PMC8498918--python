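"""Planar multi-view geometry primitives.

Textbook building blocks used by the calibration stage: normalized-DLT
homography estimation, decomposition of a plane-to-image homography into a
board pose, the single-focal reduction of Zhang's closed-form intrinsics
initialization, and similarity (Umeyama) alignment for gauge-invariant rig
comparison.
"""

from __future__ import annotations

import numpy as np


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Estimate the 3x3 homography H with dst ~ H @ src (DLT, Hartley-normalized).

    ``src`` and ``dst`` are (n, 2) arrays of corresponding points, n >= 4.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < 4:
        raise ValueError(f"homography needs >=4 correspondences, got {n}")

    def _normalize(pts):
        c = pts.mean(axis=0)
        d = np.mean(np.linalg.norm(pts - c, axis=1))
        s = np.sqrt(2) / d if d > 0 else 1.0
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])
        ph = np.column_stack([pts, np.ones(len(pts))]) @ T.T
        return ph, T

    sh, Ts = _normalize(src)
    dh, Td = _normalize(dst)

    A = np.zeros((2 * n, 9))
    A[0::2, 0:3] = sh
    A[0::2, 6:9] = -dh[:, 0:1] * sh
    A[1::2, 3:6] = sh
    A[1::2, 6:9] = -dh[:, 1:2] * sh
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    if abs(H[2, 2]) < 1e-12 * np.abs(H).max():
        raise ValueError("degenerate homography (board nearly edge-on)")
    return H / H[2, 2]


def focal_from_homographies(homographies: list[np.ndarray], principal_point: np.ndarray) -> float:
    """Closed-form focal length from plane-to-image homographies.

    Single-focal reduction of Zhang's intrinsics initialization: with the
    principal point known and f_x = f_y = f, each homography H (board plane
    z=0 -> pixels) yields two linear constraints on u = 1/f^2 through the
    orthonormality of the first two columns of [r1 r2 t].  Solved in least
    squares over all views.

    Raises ``ValueError`` when the constraint system is degenerate (e.g. all
    views fronto-parallel), which callers turn into a fallback.
    """
    cx, cy = principal_point
    shift = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    rows = []
    rhs = []
    for H in homographies:
        Hs = shift @ H
        h1, h2 = Hs[:, 0], Hs[:, 1]
        # h1' w h2 = 0 and h1' w h1 = h2' w h2 with w = diag(u, u, 1)
        rows.append(h1[0] * h2[0] + h1[1] * h2[1])
        rhs.append(-h1[2] * h2[2])
        rows.append(h1[0] ** 2 + h1[1] ** 2 - h2[0] ** 2 - h2[1] ** 2)
        rhs.append(-(h1[2] ** 2 - h2[2] ** 2))
    rows = np.asarray(rows)
    rhs = np.asarray(rhs)
    # one candidate solution per well-conditioned constraint; the median is
    # robust to the near-degenerate (fronto-parallel) views in the mix
    good = np.abs(rows) > 1e-6 * np.abs(rows).max()
    candidates = rhs[good] / rows[good]
    candidates = candidates[np.isfinite(candidates) & (candidates > 0)]
    if len(candidates) < 3:
        raise ValueError("degenerate view geometry for focal initialization")
    med = np.median(candidates)
    q1, q3 = np.percentile(candidates, [25, 75])
    if (q3 - q1) > 5.0 * med:
        # candidates do not concentrate: the views carry no perspective
        # information about the focal (e.g. all fronto-parallel)
        raise ValueError("degenerate view geometry for focal initialization")
    return float(1.0 / np.sqrt(med))


def pose_from_homography(H: np.ndarray, focal: float, principal_point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a board-plane homography into (R, t) given intrinsics.

    H maps board coordinates (X, Y, 1) on the z=0 plane to pixel coordinates.
    Returns the world(board)-to-camera rotation matrix and translation, with
    the board constrained to lie in front of the camera.
    """
    cx, cy = principal_point
    Kinv = np.array([[1 / focal, 0, -cx / focal], [0, 1 / focal, -cy / focal], [0, 0, 1.0]])
    B = Kinv @ H
    lam = 2.0 / (np.linalg.norm(B[:, 0]) + np.linalg.norm(B[:, 1]))
    if B[2, 2] * lam < 0:  # board must be in front: t_z > 0
        lam = -lam
    r1 = lam * B[:, 0]
    r2 = lam * B[:, 1]
    t = lam * B[:, 2]
    r3 = np.cross(r1, r2)
    Rapprox = np.column_stack([r1, r2, r3])
    # project onto SO(3)
    U, _, Vt = np.linalg.svd(Rapprox)
    R = U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt
    return R, t


def umeyama_alignment(src: np.ndarray, dst: np.ndarray, with_scale: bool = True) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform: dst ~ s * R @ src + t (Umeyama).

    Returns ``(s, R, t)``.  Used to compare reconstructions and rigs up to
    the gauge freedom (global rotation, translation, scale) inherent to
    multi-camera calibration.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1
    R = U @ S @ Vt
    if with_scale:
        var_s = np.mean(np.sum(xs**2, axis=1))
        s = np.trace(np.diag(D) @ S) / var_s
    else:
        s = 1.0
    t = mu_d - s * R @ mu_s
    return float(s), R, t


def orthogonalize(v: np.ndarray, against: np.ndarray) -> np.ndarray:
    """Component of ``v`` orthogonal to unit vector ``against``, normalized.

    Returns NaNs when ``v`` is (near-)parallel to ``against``.
    """
    v = np.asarray(v, dtype=float)
    against = np.asarray(against, dtype=float)
    w = v - np.sum(v * against, axis=-1, keepdims=True) * against
    n = np.linalg.norm(w, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 1e-10, w / n, np.nan)
    return out
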