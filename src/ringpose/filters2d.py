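"""Filters that clean per-camera 2D keypoint detections before triangulation.

Three complementary algorithms:

- **median filter** — flags points that deviate from a running median of the
  trajectory and re-fills them by spline interpolation; catches isolated
  single-frame glitches;
- **Viterbi filter** — treats the top-n candidate detections per frame as the
  states of a hidden Markov model (emission = detection confidence,
  transition = isotropic Gaussian on the displacement) and extracts the
  single most probable path, which corrects errors persisting over several
  frames and bridges gaps of up to ``max_gap`` frames;
- **autoencoder filter** — a small MLP that maps the vector of per-joint
  confidence scores of a frame to corrected scores, trained on synthetic
  score vectors that mimic how a keypoint detector scores visible vs.
  occluded joints; keypoints whose corrected score falls below a threshold
  are dropped so that confidently wrong detections of occluded joints do not
  poison the triangulation.

Arrays follow the package convention: a keypoint *series* is
``positions (T, J, 2)`` + ``scores (T, J)``; *candidates* are
``positions (T, J, n_cand, 2)`` + ``scores (T, J, n_cand)``; NaN = missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

LOG_ZERO = -1e18
#: default duplicate-merge radius between candidates within a frame, pixels
DEDUP_RADIUS = 7.0


# --------------------------------------------------------------------------
# median filter


def _interpolate_1d(values: np.ndarray, max_gap: int, spline: bool) -> np.ndarray:
    """Fill NaN runs of length <= max_gap from neighboring valid samples."""
    out = values.copy()
    valid = np.isfinite(out)
    if valid.sum() < 2:
        return out
    idx = np.arange(len(out))
    if spline and valid.sum() >= 4:
        interp = CubicSpline(idx[valid], out[valid])
    else:
        interp = lambda x: np.interp(x, idx[valid], out[valid])  # noqa: E731
    missing = np.flatnonzero(~valid)
    if len(missing) == 0:
        return out
    # group consecutive missing indices
    splits = np.flatnonzero(np.diff(missing) > 1) + 1
    for run in np.split(missing, splits):
        if len(run) == 0 or len(run) > max_gap:
            continue
        if run[0] == 0 or run[-1] == len(out) - 1:
            continue  # never extrapolate
        out[run] = interp(run)
    return out


def median_filter_2d(
    positions: np.ndarray,
    scores: np.ndarray | None = None,
    window: int = 7,
    offset_threshold: float = 20.0,
    spline: bool = True,
    max_gap: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Remove outliers against a running median and interpolate the gaps.

    Per joint, the x and y trajectories are median-filtered with a centered
    window; points whose Euclidean offset from the filtered trajectory
    exceeds ``offset_threshold`` pixels are removed.  Removed and
    pre-existing gaps up to ``max_gap`` frames (default: the window length)
    are filled by cubic-spline (or linear) interpolation; interpolated
    points get a score of 0.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    positions = np.asarray(positions, dtype=float)
    T, J, _ = positions.shape
    if window > T:
        raise ValueError(f"window {window} larger than series length {T}")
    if max_gap is None:
        max_gap = window
    if scores is None:
        scores = np.where(np.isfinite(positions).all(axis=2), 1.0, np.nan)
    out = positions.copy()
    out_scores = np.asarray(scores, dtype=float).copy()
    for j in range(J):
        df = pd.DataFrame(positions[:, j, :])
        med = df.rolling(window, center=True, min_periods=1).median().to_numpy()
        offset = np.linalg.norm(positions[:, j, :] - med, axis=1)
        bad = offset > offset_threshold
        out[bad, j, :] = np.nan
        was_missing = ~np.isfinite(out[:, j, :]).all(axis=1)
        for c in range(2):
            out[:, j, c] = _interpolate_1d(out[:, j, c], max_gap, spline)
        filled = was_missing & np.isfinite(out[:, j, :]).all(axis=1)
        out_scores[filled, j] = 0.0
        out_scores[~np.isfinite(out[:, j, :]).all(axis=1), j] = np.nan
    return out, out_scores


# --------------------------------------------------------------------------
# Viterbi filter


def dedup_candidates(
    positions: np.ndarray, scores: np.ndarray, radius: float = DEDUP_RADIUS
) -> tuple[np.ndarray, np.ndarray]:
    """Merge candidates within ``radius`` pixels of each other in one frame,
    keeping the highest-scoring member of each cluster.

    ``positions`` is (n, 2), ``scores`` (n,).  Returns filtered copies.
    """
    order = np.argsort(-scores)
    keep: list[int] = []
    for i in order:
        if not np.isfinite(positions[i]).all() or not np.isfinite(scores[i]):
            continue
        if all(np.linalg.norm(positions[i] - positions[k]) > radius for k in keep):
            keep.append(i)
    keep = sorted(keep)
    return positions[keep], scores[keep]


def viterbi_filter(
    cand_positions: np.ndarray,
    cand_scores: np.ndarray,
    sigma: float = 10.0,
    max_gap: int = 5,
    dedup_radius: float = DEDUP_RADIUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Most probable keypoint path through the candidate detections.

    Per joint, a hidden Markov model is built whose states at frame ``t``
    are the deduplicated candidates of that frame plus candidates carried
    over from up to ``max_gap`` previous frames with scores multiplied by
    ``2**-gap``.  Emission weight is the (adjusted) confidence score;
    transition weight is an isotropic Gaussian density on the displacement
    with standard deviation ``sigma`` pixels.  The Viterbi algorithm
    returns the exact maximum-probability path; frames
    whose selected state is a carryover are emitted as missing (the joint
    was not actually observed there).

    Parameters
    ----------
    cand_positions : (T, J, n_cand, 2) array
    cand_scores : (T, J, n_cand) array

    Returns
    -------
    positions (T, J, 2), scores (T, J)
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    cand_positions = np.asarray(cand_positions, dtype=float)
    cand_scores = np.asarray(cand_scores, dtype=float)
    T, J = cand_scores.shape[:2]
    out_pos = np.full((T, J, 2), np.nan)
    out_scores = np.full((T, J), np.nan)
    for j in range(J):
        pos_j, score_j = _viterbi_single_joint(
            cand_positions[:, j], cand_scores[:, j], sigma, max_gap, dedup_radius
        )
        out_pos[:, j] = pos_j
        out_scores[:, j] = score_j
    return out_pos, out_scores


def _viterbi_single_joint(positions, scores, sigma, max_gap, dedup_radius):
    T = positions.shape[0]
    # deduplicated observed candidates per frame
    frame_pos: list[np.ndarray] = []
    frame_score: list[np.ndarray] = []
    for t in range(T):
        valid = np.isfinite(scores[t]) & np.isfinite(positions[t]).all(axis=1)
        p, s = dedup_candidates(positions[t][valid], scores[t][valid], dedup_radius)
        frame_pos.append(p)
        frame_score.append(s)

    # state construction: observed candidates + carryovers (gap 1..max_gap)
    state_pos: list[np.ndarray] = []
    state_em: list[np.ndarray] = []  # adjusted score
    state_carry: list[np.ndarray] = []
    for t in range(T):
        ps, ss, carry = [frame_pos[t]], [frame_score[t]], [np.zeros(len(frame_pos[t]), bool)]
        for gap in range(1, max_gap + 1):
            if t - gap < 0:
                break
            ps.append(frame_pos[t - gap])
            ss.append(frame_score[t - gap] * 2.0 ** (-gap))
            carry.append(np.ones(len(frame_pos[t - gap]), bool))
        state_pos.append(np.concatenate(ps, axis=0) if ps else np.zeros((0, 2)))
        state_em.append(np.concatenate(ss) if ss else np.zeros(0))
        state_carry.append(np.concatenate(carry) if carry else np.zeros(0, bool))

    out_pos = np.full((T, 2), np.nan)
    out_score = np.full(T, np.nan)

    with np.errstate(divide="ignore"):
        log_em = [np.where(s > 0, np.log(np.maximum(s, 1e-300)), LOG_ZERO) for s in state_em]

    delta_prev = None
    back: list[np.ndarray | None] = []
    seg_start = 0
    segments: list[tuple[int, int]] = []  # (start, end) of contiguous non-empty runs

    def finish_segment(end_t):
        """Backtrack the best path over frames [seg_start, end_t)."""
        if end_t <= seg_start:
            return
        t = end_t - 1
        s = int(np.argmax(deltas[t]))
        while t >= seg_start:
            if not state_carry[t][s]:
                out_pos[t] = state_pos[t][s]
                out_score[t] = state_em[t][s]
            bp = back[t]
            s = int(bp[s]) if bp is not None else s
            t -= 1

    deltas: list[np.ndarray | None] = [None] * T
    for t in range(T):
        n = len(state_em[t])
        if n == 0:
            # path restarts after an empty frame
            if delta_prev is not None:
                finish_segment(t)
            delta_prev = None
            back.append(None)
            continue
        if delta_prev is None:
            seg_start = t
            deltas[t] = log_em[t].copy()
            back.append(None)
        else:
            disp = np.linalg.norm(
                state_pos[t][:, None, :] - state_pos[t - 1][None, :, :], axis=2
            )
            log_trans = -0.5 * (disp / sigma) ** 2
            total = delta_prev[None, :] + log_trans
            bp = np.argmax(total, axis=1)
            deltas[t] = log_em[t] + total[np.arange(n), bp]
            back.append(bp)
        delta_prev = deltas[t]
    if delta_prev is not None:
        finish_segment(T)
    return out_pos, out_score


# --------------------------------------------------------------------------
# autoencoder filter


def generate_autoencoder_training(
    n_joints: int,
    n_samples: int = 20000,
    seed: int | np.random.SeedSequence | None = 0,
    p_visible: float = 0.8,
    structured_frac: float = 0.10,
    score_sd: float = 0.3,
    flip_frac: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic per-frame confidence-score vectors with visibility labels.

    Each joint is independently visible with probability ``p_visible``;
    ``structured_frac`` of the frames instead occlude a contiguous block of
    joints (mimicking one side of the body leaving view).  Scores are drawn
    from N(1, 0.3) for visible and N(0, 0.3) for invisible joints, clipped
    to [0, 1], and 5% of scores are flipped (x -> 1 - x) to mimic false
    positives/negatives.
    """
    if n_joints < 1:
        raise ValueError("n_joints must be >= 1")
    rng = np.random.default_rng(seed)
    visible = rng.random((n_samples, n_joints)) < p_visible
    structured = rng.random(n_samples) < structured_frac
    for i in np.flatnonzero(structured):
        block = rng.integers(1, max(n_joints // 2, 1) + 1)
        start = rng.integers(0, n_joints)
        visible[i] = True
        visible[i, start : start + block] = False
    means = np.where(visible, 1.0, 0.0)
    scores = np.clip(rng.normal(means, score_sd), 0.0, 1.0)
    flip = rng.random(scores.shape) < flip_frac
    scores = np.where(flip, 1.0 - scores, scores)
    return scores, visible


class ScoreAutoencoder:
    """MLP mapping a frame's joint-score vector to corrected scores.

    Single hidden layer of ``n_joints`` tanh units trained with Adam; the
    target for each joint is its true visibility (1 visible, 0 occluded), so
    a confidently wrong score for an occluded joint is pulled toward 0.
    """

    def __init__(self, n_joints: int, seed: int = 0, max_iter: int = 500):
        from sklearn.neural_network import MLPRegressor

        self.n_joints = n_joints
        self.model = MLPRegressor(
            hidden_layer_sizes=(n_joints,),
            activation="tanh",
            solver="adam",
            max_iter=max_iter,
            random_state=seed,
        )

    def fit(self, scores: np.ndarray, visible: np.ndarray) -> "ScoreAutoencoder":
        self.model.fit(np.asarray(scores, float), np.asarray(visible, float))
        return self

    def predict(self, scores: np.ndarray) -> np.ndarray:
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        if scores.shape[1] != self.n_joints:
            raise ValueError(
                f"model trained for {self.n_joints} joints, got {scores.shape[1]}"
            )
        out = self.model.predict(np.nan_to_num(scores, nan=0.0))
        return np.clip(out, 0.0, 1.0)


def train_autoencoder(
    scores: np.ndarray, visible: np.ndarray, seed: int = 0, max_iter: int = 500
) -> ScoreAutoencoder:
    """Train the score-correction MLP on synthetic (scores, visibility) data."""
    n_joints = np.asarray(scores).shape[1]
    return ScoreAutoencoder(n_joints, seed=seed, max_iter=max_iter).fit(scores, visible)


def apply_autoencoder(
    positions: np.ndarray,
    scores: np.ndarray,
    model: ScoreAutoencoder,
    drop_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Rewrite scores with the autoencoder and drop low-confidence keypoints.

    Positions are never altered, only removed: a keypoint whose corrected
    score falls below ``drop_threshold`` is set to missing.
    """
    positions = np.asarray(positions, dtype=float)
    scores = np.asarray(scores, dtype=float)
    T, J = scores.shape
    if J != model.n_joints:
        raise ValueError(f"model trained for {model.n_joints} joints, got {J}")
    corrected = model.predict(scores)
    out_pos = positions.copy()
    out_pos[corrected < drop_threshold] = np.nan
    return out_pos, corrected
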