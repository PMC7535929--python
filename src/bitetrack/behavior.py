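"""Locomotion classification, ethograms, and trajectory statistics.

Per-frame centroid velocity separates three locomotion classes:
stationary (< 2 mm/s), walking (2–12 mm/s, boundaries inclusive), and
flight (> 12 mm/s). Run-length encoding of the per-frame labels yields an
ethogram; summary statistics per trajectory mirror the standard
surface-time / distance / mean-velocity / time-to-engorgement panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .calibration import Calibration

STATIONARY, WALKING, FLIGHT = "stationary", "walking", "flight"
LABELS = (STATIONARY, WALKING, FLIGHT)


@dataclass(frozen=True)
class LocomotionThresholds:
    v_stat_walk: float = 2.0  # mm/s
    v_walk_flight: float = 12.0  # mm/s

    def __post_init__(self) -> None:
        if not 0 < self.v_stat_walk < self.v_walk_flight:
            raise ValueError("need 0 < v_stat_walk < v_walk_flight")


@dataclass
class Ethogram:
    """Run-length encoded behavior intervals for one individual.

    Runs are stored as half-open frame intervals so that decoding exactly
    reproduces the per-frame labels; times are derived via fps. ``marks``
    holds point events such as the time of full engorgement.
    """

    runs: list[tuple[int, int, str]]  # (start_frame, end_frame_excl, label)
    fps: float
    offset_frame: int = 0
    marks: list[tuple[float, str]] = field(default_factory=list)

    @property
    def intervals(self) -> list[tuple[float, float, str]]:
        return [
            ((s + self.offset_frame) / self.fps, (e + self.offset_frame) / self.fps, lab)
            for s, e, lab in self.runs
        ]

    def decode(self) -> np.ndarray:
        n = self.runs[-1][1] if self.runs else 0
        out = np.empty(n, dtype=object)
        for s, e, lab in self.runs:
            out[s:e] = lab
        return out

    @property
    def total_time(self) -> float:
        return sum(e - s for s, e, _ in self.runs) / self.fps


def run_length_encode(labels) -> list[tuple[int, int, str]]:
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        return []
    change = np.nonzero(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(s), int(e), str(labels[s])) for s, e in zip(starts, ends)]


def compute_velocity(
    xy, calibration: Calibration, smooth_window: int = 3
) -> np.ndarray:
    """Centroid speed in mm/s from pixel positions.

    Central differences in the interior, one-sided at the endpoints, then a
    running median over ``smooth_window`` frames (odd; 1 disables
    smoothing) to suppress single-frame jitter without lagging transitions.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return np.empty(0)
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd integer")
    disp = np.empty_like(xy)
    disp[1:-1] = (xy[2:] - xy[:-2]) / 2.0
    disp[0] = xy[1] - xy[0]
    disp[-1] = xy[-1] - xy[-2]
    speed = np.hypot(disp[:, 0], disp[:, 1]) * calibration.fps * calibration.mm_per_px
    if smooth_window > 1:
        speed = median_filter(speed, size=smooth_window, mode="nearest")
    return speed


def classify_locomotion(
    velocity, thresholds: LocomotionThresholds | None = None
) -> np.ndarray:
    """Map speeds to labels: < v_stat_walk → stationary,
    [v_stat_walk, v_walk_flight] → walking (closed interval),
    > v_walk_flight → flight."""
    thr = thresholds or LocomotionThresholds()
    v = np.asarray(velocity, dtype=float)
    if np.any(v < 0):
        raise ValueError("velocities must be non-negative")
    labels = np.full(v.shape, WALKING, dtype=object)
    labels[v < thr.v_stat_walk] = STATIONARY
    labels[v > thr.v_walk_flight] = FLIGHT
    return labels


def build_ethogram(trajectory, labels, engorgement=None) -> Ethogram:
    """Run-length encode a trajectory's per-frame labels into an ethogram.

    ``trajectory`` needs ``frames`` (for the time offset) and ``fps``;
    ``labels`` must cover every trajectory frame. An engorgement result
    with a time adds an "engorged" mark.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(trajectory.frames):
        raise ValueError(
            f"{len(labels)} labels for {len(trajectory.frames)} trajectory frames"
        )
    eth = Ethogram(
        runs=run_length_encode(labels),
        fps=trajectory.fps,
        offset_frame=int(trajectory.frames[0]),
    )
    if engorgement is not None and getattr(engorgement, "engorgement_time", None) is not None:
        t0 = trajectory.frames[0] / trajectory.fps
        eth.marks.append((t0 + engorgement.engorgement_time, "engorged"))
    return eth


@dataclass
class TrajectoryStats:
    duration: float  # s, landing to departure
    surface_time: float  # s on the substrate
    distance: float  # mm covered while not in flight
    mean_velocity: float  # mm/s = distance / surface_time
    time_to_engorgement: float | None = None


def trajectory_stats(
    trajectory, velocity, labels, engorgement, calibration: Calibration
) -> TrajectoryStats:
    """Summary statistics of one landing-to-departure episode.

    Distance sums per-step displacements whose arrival frame is not
    labeled flight; mean velocity is distance over surface time (the full
    landing-to-departure span, since the animal is on the substrate for
    the whole trajectory).
    """
    labels = np.asarray(labels, dtype=object)
    duration = trajectory.duration
    if len(trajectory.xy) >= 2:
        steps = np.hypot(*np.diff(trajectory.xy, axis=0).T)
        keep = labels[1:] != FLIGHT
        distance = float(calibration.px_to_mm(steps[keep].sum()))
    else:
        distance = 0.0
    t_eng = getattr(engorgement, "engorgement_time", None) if engorgement else None
    return TrajectoryStats(
        duration=duration,
        surface_time=duration,
        distance=distance,
        mean_velocity=distance / duration if duration > 0 else 0.0,
        time_to_engorgement=t_eng,
    )


def bout_statistics(trajectories) -> dict:
    """Per-individual bout bookkeeping: number of landing-to-departure
    bouts and their durations in seconds."""
    lengths = [t.duration for t in trajectories]
    return {"n_bouts": len(lengths), "bout_lengths": lengths}


def occupancy_map(xy, frame_size, bin_px: int) -> np.ndarray:
    """2-D histogram of detection positions on the substrate.

    Returns counts with shape (ceil(h/bin), ceil(w/bin)); the sum of all
    bins equals the number of detections.
    """
    if bin_px <= 0:
        raise ValueError("bin_px must be positive")
    h, w = frame_size
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    y_edges = np.arange(0, h + bin_px, bin_px)
    x_edges = np.arange(0, w + bin_px, bin_px)
    counts, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(y_edges, x_edges))
    return counts.astype(int)


def ethogram_table(ethograms: dict[object, Ethogram]) -> pd.DataFrame:
    """Flatten per-individual ethograms into (individual, t_start_s,
    t_end_s, label) rows, marks included with t_start == t_end."""
    rows = []
    for ind, eth in ethograms.items():
        for t0, t1, lab in eth.intervals:
            rows.append((ind, t0, t1, lab))
        for t, lab in eth.marks:
            rows.append((ind, t, t, lab))
    return pd.DataFrame(rows, columns=["individual", "t_start_s", "t_end_s", "label"])
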