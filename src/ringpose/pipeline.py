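"""Project-level orchestration: layout, configuration, and batch stages.

A *project* is a directory tree whose sessions (at a configurable nesting
depth) each hold the standard slots::

    <session>/
        calibration/          board-corner detection tables; calibration.json
        pose-2d/              raw keypoint candidate tables
        pose-2d-filtered/     filtered keypoint series
        pose-3d/              triangulated trajectories + limb-length sidecar
        angles/               joint-angle tables

Stages (``calibrate``, ``filter``, ``triangulate``, ``angles``) run over all
sessions, check that their upstream outputs exist, skip work whose outputs
are already present unless forced, and drop a frozen copy of the effective
configuration next to everything they write.  All randomness derives from a
single project seed through ``numpy.random.SeedSequence`` spawning, so two
runs with the same seed produce bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .calibration import BoardGeometry, calibrate_rig
from .camera import CameraRig
from .filters2d import (
    apply_autoencoder,
    generate_autoencoder_training,
    median_filter_2d,
    train_autoencoder,
    viterbi_filter,
)
from .kinematics import chain_angles
from .triangulation import (
    Skeleton,
    median_filter_3d,
    triangulate_regularized,
    triangulate_series,
)

logger = logging.getLogger(__name__)

STAGES = ("calibrate", "filter", "triangulate", "angles")
SLOTS = ("calibration", "pose-2d", "pose-2d-filtered", "pose-3d", "angles")


class PipelineError(RuntimeError):
    pass


@dataclass
class CalibrationConfig:
    board_squares_x: int = 6
    board_squares_y: int = 6
    square_size: float = 0.5
    marker_size: float = 0.375
    image_width: int = 832
    image_height: int = 632
    n_iter: int = 12
    mu_start: float = 15.0
    mu_end: float = 1.0
    anchor_scale: bool = True


@dataclass
class FilterConfig:
    median: bool = False
    window: int = 7
    offset_threshold: float = 20.0
    spline: bool = True
    viterbi: bool = True
    viterbi_sigma: float = 10.0
    max_gap: int = 5
    dedup_radius: float = 7.0
    autoencoder: bool = True
    drop_threshold: float = 0.5
    autoencoder_samples: int = 20000


@dataclass
class TriangulationConfig:
    method: str = "regularized"  # linear | ransac | regularized
    beta_time: float = 2.0
    alpha_limb: float = 2.0
    derivative_order: int = 2
    robust_norm: str = "soft_l1"
    robust_scale: float = 10.0
    reproj_drop: float = 20.0
    median_window: int = 0  # 0 disables the 3D median filter
    chunk_size: int = 500
    chunk_overlap: int = 50
    frame_rate: float = 100.0


@dataclass
class AnglesConfig:
    chains: list[list[str]] = field(default_factory=list)
    # optional [origin, anterior, dorsal] keypoints defining the body frame
    body_reference: list[str] = field(default_factory=list)


@dataclass
class SkeletonConfig:
    joints: list[str] = field(default_factory=list)
    limbs: list[list[str]] = field(default_factory=list)
    flexible: list[list[str]] = field(default_factory=list)


@dataclass
class ProjectConfig:
    """All pipeline parameters, materialized with defaults.

    Unknown keys in a config file are rejected so typos fail loudly; the
    effective config is frozen (JSON) next to every stage output for
    provenance.
    """

    path: str = "."
    nesting_depth: int = 1
    seed: int = 0
    camera_regex: str = r"cam\w+"
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    triangulation: TriangulationConfig = field(default_factory=TriangulationConfig)
    angles: AnglesConfig = field(default_factory=AnglesConfig)
    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "ProjectConfig":
        cfg = cls()
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in sections:
                raise PipelineError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if dataclasses.is_dataclass(current):
                known = {f.name for f in dataclasses.fields(current)}
                for k, v in value.items():
                    if k not in known:
                        raise PipelineError(f"unknown config key {key}.{k}")
                    setattr(current, k, v)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "ProjectConfig":
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        cfg = cls.from_dict(data)
        if not Path(cfg.path).is_absolute():
            # the project root is wherever the config file lives
            cfg.path = str(path.parent)
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def freeze(self, directory: Path) -> None:
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config_used.json").write_text(json.dumps(self.to_dict(), indent=1))

    def board(self) -> BoardGeometry:
        c = self.calibration
        return BoardGeometry(c.board_squares_x, c.board_squares_y, c.square_size, c.marker_size)

    def build_skeleton(self, joints: list[str]) -> Skeleton:
        sk = self.skeleton
        if sk.joints:
            joints = sk.joints
        limbs = [tuple(l) for l in sk.limbs]
        chains = self.angles.chains
        return Skeleton(
            joints=joints,
            limbs=limbs,
            chains=chains,
            flexible=[tuple(l) for l in sk.flexible],
        )


def discover_sessions(config: ProjectConfig) -> list[Path]:
    """Sessions at the configured nesting depth, lexicographic order."""
    root = Path(config.path)
    if not root.exists():
        raise PipelineError(f"project root {root} does not exist")
    if config.nesting_depth == 0:
        candidates = [root]
    else:
        pattern = "/".join("*" * 1 for _ in range(config.nesting_depth))
        candidates = sorted(p for p in root.glob(pattern) if p.is_dir())
    sessions = [p for p in candidates if any((p / slot).exists() for slot in SLOTS)]
    if not sessions:
        raise PipelineError(f"no sessions found under {root}")
    return sessions


def _session_seed(config: ProjectConfig, session: Path, stage: str) -> np.random.SeedSequence:
    """Deterministic per-(session, stage) seed derived from the project seed."""
    label = f"{session.name}/{stage}"
    digest = sum(ord(c) * (i + 1) for i, c in enumerate(label)) % (2**16)
    return np.random.SeedSequence([config.seed, digest])


def _setup_session_logging(session: Path) -> logging.Handler:
    handler = logging.FileHandler(session / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("ringpose").addHandler(handler)
    return handler


def run_stage(stage: str, config: ProjectConfig, force: bool = False) -> dict:
    """Run one pipeline stage over every session of the project.

    Returns a summary dict with per-session timing and outputs.  Raises
    :class:`PipelineError` when upstream outputs are missing.
    """
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; expected one of {STAGES}")
    sessions = discover_sessions(config)
    summary: dict = {"stage": stage, "sessions": {}}
    for session in sessions:
        handler = _setup_session_logging(session)
        t0 = time.time()
        try:
            runner = globals()[f"_run_{stage}"]
            result = runner(config, session, force)
        finally:
            logging.getLogger("ringpose").removeHandler(handler)
            handler.close()
        result["seconds"] = round(time.time() - t0, 3)
        summary["sessions"][str(session)] = result
        logger.info("stage %s on %s: %s", stage, session, result)
    return summary


def _run_calibrate(config: ProjectConfig, session: Path, force: bool) -> dict:
    cal_dir = session / "calibration"
    out = cal_dir / "calibration.json"
    if out.exists() and not force:
        return {"skipped": True, "output": str(out)}
    files = sorted(cal_dir.glob("*.csv")) + sorted(cal_dir.glob("*.h5"))
    files = [f for f in files if f.name != "calibration.json"]
    if not files:
        raise PipelineError(f"{session}: no calibration detection tables in {cal_dir}")
    det = pd.concat([rio.read_table(f) for f in files], ignore_index=True)
    c = config.calibration
    sizes = {name: (c.image_width, c.image_height) for name in det["camera"].unique()}
    seed = _session_seed(config, session, "calibrate")
    rig, points3d, summ = calibrate_rig(
        det,
        config.board(),
        sizes,
        n_iter=c.n_iter,
        mu_start=c.mu_start,
        mu_end=c.mu_end,
        seed=seed,
        anchor_scale=c.anchor_scale,
    )
    rig.metadata["mean_reprojection_error"] = summ.final_error
    rig.save(out)
    config.freeze(cal_dir)
    return {
        "skipped": False,
        "output": str(out),
        "mean_reprojection_error": summ.final_error,
        "n_observations": summ.n_observations,
    }


def _run_filter(config: ProjectConfig, session: Path, force: bool) -> dict:
    in_dir = session / "pose-2d"
    out_dir = session / "pose-2d-filtered"
    if not in_dir.exists():
        raise PipelineError(f"{session}: missing upstream stage output {in_dir} (run detection/simulate first)")
    files = sorted(in_dir.glob("*.csv")) + sorted(in_dir.glob("*.h5"))
    if not files:
        raise PipelineError(f"{session}: no keypoint tables in {in_dir}")
    fc = config.filter
    seed_seq = _session_seed(config, session, "filter")
    seeds = seed_seq.spawn(len(files))
    written = []
    for f, sseq in zip(files, seeds):
        out = out_dir / f.with_suffix(".csv").name
        if out.exists() and not force:
            continue
        df = rio.read_table(f)
        pos_c, score_c, cameras, joints = rio.table_to_candidates(df)
        C, T, J = score_c.shape[:3]
        series_pos = np.full((C, T, J, 2), np.nan)
        series_score = np.full((C, T, J), np.nan)
        for ci in range(C):
            if fc.viterbi:
                p, s = viterbi_filter(
                    pos_c[ci], score_c[ci], sigma=fc.viterbi_sigma,
                    max_gap=fc.max_gap, dedup_radius=fc.dedup_radius,
                )
            else:  # top-ranked candidate only
                p, s = pos_c[ci, :, :, 0, :].copy(), score_c[ci, :, :, 0].copy()
            if fc.median:
                p, s = median_filter_2d(
                    p, s, window=fc.window,
                    offset_threshold=fc.offset_threshold, spline=fc.spline,
                )
            series_pos[ci], series_score[ci] = p, s
        if fc.autoencoder:
            rng_seed = int(sseq.generate_state(1)[0] % (2**31))
            train_scores, train_vis = generate_autoencoder_training(
                J, fc.autoencoder_samples, seed=sseq
            )
            model = train_autoencoder(train_scores, train_vis, seed=rng_seed)
            for ci in range(C):
                scores_in = np.nan_to_num(series_score[ci], nan=0.0)
                series_pos[ci], series_score[ci] = apply_autoencoder(
                    series_pos[ci], scores_in, model, drop_threshold=fc.drop_threshold
                )
        rio.write_table(rio.series_to_table(series_pos, series_score, cameras, joints), out)
        written.append(str(out))
    config.freeze(out_dir)
    return {"skipped": not written, "outputs": written}


def _run_triangulate(config: ProjectConfig, session: Path, force: bool) -> dict:
    cal_file = session / "calibration" / "calibration.json"
    if not cal_file.exists():
        raise PipelineError(f"{session}: missing calibration (run the calibrate stage first)")
    in_dir = session / "pose-2d-filtered"
    if not in_dir.exists():
        raise PipelineError(f"{session}: missing filtered 2D keypoints (run the filter stage first)")
    files = sorted(in_dir.glob("*.csv")) + sorted(in_dir.glob("*.h5"))
    if not files:
        raise PipelineError(f"{session}: no filtered keypoint tables in {in_dir}")
    rig = CameraRig.load(cal_file)
    tc = config.triangulation
    out_dir = session / "pose-3d"
    written = []
    for f in files:
        out = out_dir / f.with_suffix(".csv").name
        if out.exists() and not force:
            continue
        df = rio.read_table(f)
        pos, _scores, cameras, joints = rio.table_to_series(df)
        order = [cameras.index(n) for n in rig.names if n in cameras]
        pos = pos[order]
        joints_used = list(joints)
        if tc.method == "regularized":
            skeleton = config.build_skeleton(joints_used)
            traj = triangulate_regularized(
                pos, rig, skeleton,
                beta_time=tc.beta_time, alpha_limb=tc.alpha_limb,
                derivative_order=tc.derivative_order, robust_norm=tc.robust_norm,
                robust_scale=tc.robust_scale, reproj_drop=tc.reproj_drop,
                frame_rate=tc.frame_rate, chunk_size=tc.chunk_size,
                chunk_overlap=tc.chunk_overlap,
            )
            if traj.limb_lengths:
                side = out_dir / (out.stem + "_limb_lengths.json")
                out_dir.mkdir(parents=True, exist_ok=True)
                side.write_text(json.dumps(
                    {f"{a}--{b}": v for (a, b), v in traj.limb_lengths.items()}, indent=1
                ))
        else:
            traj = triangulate_series(
                pos, rig, joints_used, frame_rate=tc.frame_rate,
                method="ransac" if tc.method == "ransac" else "linear",
            )
        if tc.median_window:
            traj = median_filter_3d(traj, tc.median_window)
        rio.write_table(rio.trajectory_to_table(traj), out)
        written.append(str(out))
    config.freeze(out_dir)
    return {"skipped": not written, "outputs": written}


def _run_angles(config: ProjectConfig, session: Path, force: bool) -> dict:
    in_dir = session / "pose-3d"
    if not in_dir.exists():
        raise PipelineError(f"{session}: missing 3D trajectories (run the triangulate stage first)")
    files = [f for f in sorted(in_dir.glob("*.csv")) if not f.stem.endswith("_limb_lengths")]
    if not files:
        raise PipelineError(f"{session}: no trajectory tables in {in_dir}")
    if not config.angles.chains:
        raise PipelineError("no kinematic chains configured under [angles].chains")
    out_dir = session / "angles"
    written = []
    for f in files:
        out = out_dir / f.name
        if out.exists() and not force:
            continue
        traj = rio.table_to_trajectory(rio.read_table(f), config.triangulation.frame_rate)
        body_frame = None
        if config.angles.body_reference:
            from .kinematics import body_frame_from_keypoints

            body_frame = body_frame_from_keypoints(traj, *config.angles.body_reference)
        tables = []
        for chain in config.angles.chains:
            series = chain_angles(traj, chain, body_frame=body_frame)
            tables.append(rio.angles_to_table(series))
        rio.write_table(pd.concat(tables, ignore_index=True), out)
        written.append(str(out))
    config.freeze(out_dir)
    return {"skipped": not written, "outputs": written}


def simulate_project(
    root: str | Path,
    config: ProjectConfig | None = None,
    n_cameras: int = 6,
    n_board_frames: int = 120,
    n_frames: int = 200,
    noise_px: float = 1.0,
    seed: int = 0,
) -> Path:
    """Write a complete synthetic project: calibration detections, keypoint
    candidates, and ground truth, in the standard session layout."""
    from .synthetic import (
        make_walker_skeleton,
        simulate_articulated_walker,
        simulate_board_sequence,
        simulate_detections,
        simulate_rig,
    )

    root = Path(root)
    session = root / "session1"
    if config is None:
        config = ProjectConfig()
    config.path = str(root)
    board = config.board()
    # working distance chosen so the board spans ~35% of the image width
    focal = 600.0
    extent = board.squares_x * board.square_size
    radius = focal * extent / (0.35 * config.calibration.image_width)
    rig = simulate_rig(n_cameras=n_cameras, radius=radius, focal=focal,
                       image_size=(config.calibration.image_width, config.calibration.image_height))
    sseq = np.random.SeedSequence(seed)
    s_board, s_walk, s_det = sseq.spawn(3)
    det, _truth = simulate_board_sequence(rig, board, n_frames=n_board_frames,
                                          noise_px=noise_px, seed=s_board)
    rio.write_table(det, session / "calibration" / "board_detections.csv")

    skeleton = make_walker_skeleton(n_legs=2, joints_per_leg=4)
    traj, skeleton = simulate_articulated_walker(
        skeleton, n_frames=n_frames, frame_rate=config.triangulation.frame_rate,
        segment_length=board.square_size, body_radius=1.6 * board.square_size,
        seed=s_walk,
    )
    cand_pos, cand_scores = simulate_detections(
        traj, rig, noise_px=noise_px, n_candidates=2, missing_frac=0.02, seed=s_det
    )
    table = rio.candidates_to_table(cand_pos, cand_scores, rig.names, skeleton.joints)
    rio.write_table(table, session / "pose-2d" / "keypoints.csv")
    rio.write_table(rio.trajectory_to_table(traj), session / "ground-truth" / "trajectory.csv")

    config.angles.chains = [list(c) for c in skeleton.chains]
    config.skeleton.joints = list(skeleton.joints)
    config.skeleton.limbs = [list(l) for l in skeleton.limbs]
    (root / "config.json").write_text(json.dumps(config.to_dict(), indent=1))
    return root


def summarize_project(config: ProjectConfig) -> dict:
    """Per-session inventory of outputs and headline quality numbers."""
    out: dict = {}
    for session in discover_sessions(config):
        info: dict = {}
        cal = session / "calibration" / "calibration.json"
        if cal.exists():
            rig = CameraRig.load(cal)
            info["n_cameras"] = len(rig)
            err = rig.metadata.get("mean_reprojection_error")
            if err is not None:
                info["mean_reprojection_error"] = err
        for slot in SLOTS[1:]:
            d = session / slot
            if d.exists():
                info[slot] = len(list(d.glob("*.csv")))
        out[str(session)] = info
    return out
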