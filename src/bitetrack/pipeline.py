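"""End-to-end orchestration: frames in, behavioral tables out.

Stages: background estimation → detection → linking → trajectory
segmentation → per-trajectory cropping and body-shape measurement →
engorgement classification → velocity / locomotion labels → ethograms and
summary statistics. Every output row carries the frame and track id it
came from, and a machine-readable manifest records the configuration hash
and seed of the run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import (
    LocomotionThresholds,
    build_ethogram,
    classify_locomotion,
    compute_velocity,
    ethogram_table,
    trajectory_stats,
)
from .bodyshape import (
    AreaSeries,
    EngorgementCriteria,
    detect_engorgement,
    extract_body_shape,
)
from .calibration import Calibration
from .tracking import (
    LinkParams,
    crop_sequences,
    detect_mosquitoes,
    estimate_background,
    link_detections,
    segment_trajectories,
    tracks_to_dataframe,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    calibration: Calibration = field(default_factory=Calibration)
    link: LinkParams = field(default_factory=LinkParams)
    locomotion: LocomotionThresholds = field(default_factory=LocomotionThresholds)
    engorgement: EngorgementCriteria = field(default_factory=EngorgementCriteria)
    genus: str = "aedes"
    gap_s: float = 1.0
    box_size: int = 128
    background_stride: int = 5
    shape_stride: int = 1  # measure body shape every k-th trajectory frame
    smooth_window: int = 3
    output_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        nested = {
            "calibration": Calibration,
            "link": LinkParams,
            "locomotion": LocomotionThresholds,
            "engorgement": EngorgementCriteria,
        }
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, val in d.items():
            if key in nested and isinstance(val, dict):
                sub_known = {f.name for f in dataclasses.fields(nested[key])}
                sub_unknown = set(val) - sub_known
                if sub_unknown:
                    raise ConfigError(
                        f"unknown keys in {key!r}: {sorted(sub_unknown)}"
                    )
                try:
                    kwargs[key] = nested[key](**val)
                except (TypeError, ValueError) as e:
                    raise ConfigError(f"invalid {key!r} section: {e}") from e
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    tracks: list
    trajectories: list
    tracks_table: pd.DataFrame
    shapes_table: pd.DataFrame
    engorgement_table: pd.DataFrame
    ethogram: pd.DataFrame
    stats_table: pd.DataFrame
    manifest: dict


def load_frames(input_path) -> np.ndarray:
    """Read a frame stack from a multi-page TIFF or a directory of
    numbered PNG/TIFF files (sorted by name)."""
    p = Path(input_path)
    if p.is_dir():
        files = sorted(
            f for f in p.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise PipelineError(f"input stage: no frames found in {p}")
        import imageio.v3 as iio

        return np.stack([iio.imread(f) for f in files])
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(p))
    raise PipelineError(f"input stage: unsupported input {p}")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise PipelineError(f"{name} stage: {exc}") from exc
            logger.info("stage %-12s %.2f s", name, dt)

    return _Ctx()


def run_pipeline(
    config: PipelineConfig, frames=None, input_path=None, background=None
) -> PipelineResult:
    """Execute detect → link → segment → crop → shape → engorge → behave.

    ``frames`` is an (n, h, w) array; alternatively ``input_path`` points
    to a TIFF stack or a directory of per-frame images. ``background``
    is an optional empty-substrate image (e.g. acquired before releasing
    the animals); when omitted, a strided temporal median is used, which
    assumes each pixel is background most of the time. Writes all tables
    plus a run manifest to ``config.output_dir`` when set.
    """
    if frames is None:
        if input_path is None:
            raise PipelineError("input stage: no frames or input path given")
        frames = load_frames(input_path)
    frames = np.asarray(frames)
    if frames.ndim != 3 or len(frames) == 0:
        raise PipelineError("input stage: expected a non-empty (n, h, w) stack")
    cal = config.calibration
    fps = cal.fps

    with _stage("background"):
        if background is None:
            background = estimate_background(frames, stride=config.background_stride)
        background = np.asarray(background, dtype=float)

    with _stage("detect"):
        detections = [
            detect_mosquitoes(f, background, config.link, cal, frame_index=i)
            for i, f in enumerate(frames)
        ]
        n_det = sum(len(d) for d in detections)
        logger.info("detections: %d in %d frames", n_det, len(frames))

    with _stage("link"):
        tracks = link_detections(detections, config.link, cal, fps)

    with _stage("segment"):
        trajectories = []
        for t in tracks:
            trajectories.extend(segment_trajectories(t, fps, config.gap_s))

    shape_rows = []
    engorge_rows = []
    ethograms = {}
    stats_rows = []
    for k, traj in enumerate(trajectories):
        with _stage(f"shape[{k}]"):
            crops = crop_sequences(frames, traj, config.box_size)
            idx = np.arange(0, len(traj), config.shape_stride)
            areas = []
            for j in idx:
                try:
                    shape = extract_body_shape(crops[j], cal)
                except ValueError:
                    continue
                areas.append((int(traj.frames[j]), shape.area, shape.width))
            for f, a, wd in areas:
                shape_rows.append((traj.track_id, k, f, a, wd))

        with _stage(f"engorge[{k}]"):
            result = None
            if areas:
                series = AreaSeries(
                    fps=fps / config.shape_stride,
                    values=np.array([a for _, a, _ in areas]),
                )
                result = detect_engorgement(series, config.genus, config.engorgement)
                traj.engorgement = result
                engorge_rows.append(
                    (
                        traj.track_id,
                        k,
                        result.engorged,
                        result.fold_expansion,
                        result.p90_area,
                        result.engorgement_time,
                    )
                )

        with _stage(f"behave[{k}]"):
            if len(traj) >= 2:
                vel = compute_velocity(traj.xy, cal, config.smooth_window)
            else:
                vel = np.zeros(len(traj))
            labels = classify_locomotion(vel, config.locomotion)
            traj.labels = labels
            ethograms[(traj.track_id, k)] = build_ethogram(traj, labels, traj.engorgement)
            st = trajectory_stats(traj, vel, labels, traj.engorgement, cal)
            stats_rows.append(
                (
                    traj.track_id,
                    k,
                    traj.start_frame,
                    traj.end_frame,
                    st.duration,
                    st.surface_time,
                    st.distance,
                    st.mean_velocity,
                    st.time_to_engorgement,
                )
            )

    tracks_table = tracks_to_dataframe(tracks)
    shapes_table = pd.DataFrame(
        shape_rows, columns=["track_id", "trajectory", "frame", "area_mm2", "width_mm"]
    )
    engorgement_table = pd.DataFrame(
        engorge_rows,
        columns=["track_id", "trajectory", "engorged", "fold", "p90_area", "t_engorge_s"],
    )
    eth_table = ethogram_table(ethograms)
    stats_table = pd.DataFrame(
        stats_rows,
        columns=[
            "track_id",
            "trajectory",
            "start_frame",
            "end_frame",
            "duration_s",
            "surface_time_s",
            "distance_mm",
            "mean_velocity_mm_s",
            "time_to_engorgement_s",
        ],
    )

    cfg_dict = config.to_dict()
    cfg_dict.pop("output_dir", None)  # location, not science: keep reruns comparable
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "package": "bitetrack",
        "version": __version__,
        "numpy": np.__version__,
        "seed": config.seed,
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_frames": int(len(frames)),
        "n_detections": int(n_det),
        "n_tracks": len(tracks),
        "n_trajectories": len(trajectories),
    }

    result = PipelineResult(
        tracks=tracks,
        trajectories=trajectories,
        tracks_table=tracks_table,
        shapes_table=shapes_table,
        engorgement_table=engorgement_table,
        ethogram=eth_table,
        stats_table=stats_table,
        manifest=manifest,
    )
    if config.output_dir:
        write_result(result, config.output_dir)
    return result


def write_result(result: PipelineResult, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    kw = dict(index=False, float_format="%.6g")
    result.tracks_table.to_csv(out / "tracks.csv", **kw)
    result.shapes_table.to_csv(out / "shapes.csv", **kw)
    result.engorgement_table.to_csv(out / "engorgement.csv", **kw)
    result.ethogram.to_csv(out / "ethogram.csv", **kw)
    result.stats_table.to_csv(out / "stats.csv", **kw)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
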