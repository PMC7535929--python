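"""Ground-truthed synthetic data: image scenes, area series, pose tracks.

The scene generator emulates top-down transmitted-light recordings of
mosquitoes on a bright, flat bite substrate: each agent is a dark filled
ellipse (the body) with six thin line legs and a short proboscis, moving
according to a per-agent behavior program. Velocities are sampled inside
each locomotion class with a 10% margin from the 2 and 12 mm/s decision
thresholds so ground-truth labels are unambiguous; flight is rendered as
absence from the substrate (the camera images only the substrate). During
feeding the minor body axis dilates along a smooth logistic ramp,
mimicking abdominal engorgement.

All generators are fully determined by their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import FLIGHT, STATIONARY, WALKING
from .bodyshape import AreaSeries
from .calibration import Calibration
from .pose import PoseTrack

FEEDING = "feeding"
BEHAVIORS = (STATIONARY, WALKING, FLIGHT, FEEDING)

# velocity classes with a 10% margin from the 2 / 12 mm/s thresholds
_WALK_SPEED_RANGE = (2.2, 10.8)  # mm/s


@dataclass
class SceneConfig:
    """Parameters of a synthetic substrate scene."""

    frame_size: tuple[int, int] = (512, 512)  # (h, w) px
    fps: float = 25.0
    n_agents: int = 1
    # per-agent list of (behavior, duration_s); None -> 10 s walking each
    behavior_program: list | None = None
    body_axes: tuple[float, float] = (1.5, 0.5)  # mm semi-axes (major, minor)
    leg_length: float = 2.0  # mm
    proboscis_length: float = 0.5  # mm
    background_level: float = 200.0
    agent_level: float = 60.0
    noise_sd: float = 0.0
    calibration: float = 25.0  # um per px
    seed: int = 0
    feed_dilation: float = 1.5  # minor-axis fold at full engorgement
    feed_ramp_s: float = 5.0
    heading_jitter: float = 0.02  # rad/frame sd of the walking heading
    # optional deterministic geometry (px positions, radians); else seeded
    init_positions: list | None = None
    init_headings: list | None = None

    def __post_init__(self) -> None:
        h, w = self.frame_size
        if h <= 0 or w <= 0:
            raise ValueError("frame_size must be positive")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_agents < 0:
            raise ValueError("n_agents must be >= 0")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")
        if self.agent_level >= self.background_level:
            raise ValueError("agents must be darker than the background")
        if self.behavior_program is not None:
            if len(self.behavior_program) != self.n_agents:
                raise ValueError("behavior_program must list one program per agent")
            for prog in self.behavior_program:
                for beh, dur in prog:
                    if beh not in BEHAVIORS:
                        raise ValueError(f"unknown behavior {beh!r}")
                    if dur <= 0:
                        raise ValueError("segment durations must be positive")

    @property
    def cal(self) -> Calibration:
        return Calibration(um_per_px=self.calibration, fps=self.fps)


@dataclass
class GroundTruth:
    """Exact rendering record of a synthetic scene.

    ``records`` has one row per rendered agent per frame it is on the
    substrate: frame, agent_id, x_px, y_px, behavior, area_mm2. The
    centroid is the intensity-weighted centroid of the rendered
    silhouette — what an ideal detector would measure.
    """

    records: pd.DataFrame
    engorged: dict[int, bool]
    engorgement_time: dict[int, float | None]

    def agent_track(self, agent_id: int) -> pd.DataFrame:
        return self.records[self.records.agent_id == agent_id].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GroundTruth":
        return cls(records=pd.read_csv(path), engorged={}, engorgement_time={})


def _ellipse_mask(shape, center, a_px, b_px, theta):
    """Boolean mask of a rotated filled ellipse, plus its bounding window."""
    h, w = shape
    cx, cy = center
    r = max(a_px, b_px) + 2
    x0, x1 = max(int(cx - r), 0), min(int(cx + r) + 1, w)
    y0, y1 = max(int(cy - r), 0), min(int(cy + r) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx, dy = xs - cx, ys - cy
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    mask = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    return mask, (y0, y1, x0, x1)

_LEG_ANGLES = np.deg2rad([45, 90, 135, -45, -90, -135])


def _line_pixels(p0, p1, shape):
    """Integer pixels of a 1-px-wide segment (dense sampling)."""
    n = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]))) * 2 + 2
    xs = np.round(np.linspace(p0[0], p1[0], n)).astype(int)
    ys = np.round(np.linspace(p0[1], p1[1], n)).astype(int)
    keep = (xs >= 0) & (xs < shape[1]) & (ys >= 0) & (ys < shape[0])
    return ys[keep], xs[keep]


def _render_agent(canvas, center, theta, a_px, b_px, leg_px, prob_px, level):
    """Draw one agent; returns the (row, col) pixel coordinates it covers."""
    h, w = canvas.shape
    out = _ellipse_mask((h, w), center, a_px, b_px, theta)
    rows, cols = [], []
    if out is not None:
        mask, (y0, y1, x0, x1) = out
        rr, cc = np.nonzero(mask)
        rows.append(rr + y0)
        cols.append(cc + x0)
    cx, cy = center
    c, s = np.cos(theta), np.sin(theta)
    for phi in _LEG_ANGLES:
        direction = np.array([np.cos(theta + phi), np.sin(theta + phi)])
        # attachment on the ellipse boundary along that direction
        dc, ds = np.cos(phi), np.sin(phi)
        rad = 1.0 / np.sqrt((dc / a_px) ** 2 + (ds / b_px) ** 2)
        p0 = np.array([cx, cy]) + rad * direction
        p1 = p0 + leg_px * direction
        rr, cc = _line_pixels(p0, p1, (h, w))
        rows.append(rr)
        cols.append(cc)
    nose = np.array([cx + a_px * c, cy + a_px * s])
    tip = nose + prob_px * np.array([c, s])
    rr, cc = _line_pixels(nose, tip, (h, w))
    rows.append(rr)
    cols.append(cc)
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    canvas[rr, cc] = level
    return rr, cc


def generate_scene(config: SceneConfig):
    """Render a synthetic image sequence with exact ground truth.

    Returns (frames, ground_truth): frames is a uint8 array
    (n_frames, h, w); the ground truth records every rendered agent per
    frame with its silhouette centroid, behavior label, and body area.
    """
    rng = np.random.default_rng(config.seed)
    cal = config.cal
    h, w = config.frame_size
    a_px = cal.mm_to_px(config.body_axes[0])
    b0_px = cal.mm_to_px(config.body_axes[1])
    leg_px = cal.mm_to_px(config.leg_length)
    prob_px = cal.mm_to_px(config.proboscis_length)
    # reflect before any appendage reaches the frame edge so rendered
    # silhouettes (and hence ground-truth centroids) are never clipped
    margin = float(a_px + leg_px + 2)

    programs = config.behavior_program
    if programs is None:
        programs = [[(WALKING, 10.0)] for _ in range(config.n_agents)]
    total_s = max((sum(d for _, d in p) for p in programs), default=0.0)
    n_frames = int(round(total_s * config.fps))

    # initial geometry
    positions, headings = [], []
    for i in range(config.n_agents):
        if config.init_positions is not None:
            positions.append(np.array(config.init_positions[i], dtype=float))
        else:
            positions.append(
                rng.uniform([margin, margin], [w - margin, h - margin])
            )
        if config.init_headings is not None:
            headings.append(float(config.init_headings[i]))
        else:
            headings.append(float(rng.uniform(0, 2 * np.pi)))

    # expand programs to per-frame behavior / speed / minor-axis schedules
    schedules = []
    for i, prog in enumerate(programs):
        beh = np.empty(n_frames, dtype=object)
        speed = np.zeros(n_frames)  # px / frame
        b_axis = np.full(n_frames, b0_px)
        f = 0
        for seg_beh, seg_dur in prog:
            seg_n = int(round(seg_dur * config.fps))
            seg_n = min(seg_n, n_frames - f)
            sl = slice(f, f + seg_n)
            beh[sl] = seg_beh
            if seg_beh == WALKING:
                v_mm_s = rng.uniform(*_WALK_SPEED_RANGE)
                speed[sl] = cal.mm_to_px(v_mm_s) / config.fps
            elif seg_beh == FEEDING:
                ramp_n = max(1, int(round(min(config.feed_ramp_s, seg_dur) * config.fps)))
                t = np.arange(seg_n)
                frac = 1.0 / (1.0 + np.exp(-(t - ramp_n / 2.0) / (ramp_n / 10.0)))
                b_axis[sl] = b0_px * (1.0 + (config.feed_dilation - 1.0) * frac)
                b_axis[f + seg_n :] = b_axis[f + seg_n - 1]
            f += seg_n
        if f < n_frames:
            beh[f:] = beh[f - 1] if f > 0 else STATIONARY
        schedules.append({"behavior": beh, "speed": speed, "b_axis": b_axis})

    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    records = []
    engorged = {}
    engorge_time = {}
    # engorgement time = end of the dilation ramp of the feeding segment
    for i, prog in enumerate(programs):
        engorged[i] = any(b == FEEDING for b, _ in prog)
        engorge_time[i] = None
        t_start = 0.0
        for b, d in prog:
            if b == FEEDING:
                engorge_time[i] = t_start + min(config.feed_ramp_s, d)
                break
            t_start += d

    for f in range(n_frames):
        canvas = np.full((h, w), float(config.background_level))
        for i in range(config.n_agents):
            sched = schedules[i]
            beh = sched["behavior"][f]
            if beh == FLIGHT:
                continue
            if beh == WALKING and sched["speed"][f] > 0:
                if config.heading_jitter > 0:
                    headings[i] += rng.normal(0.0, config.heading_jitter)
                step = sched["speed"][f] * np.array(
                    [np.cos(headings[i]), np.sin(headings[i])]
                )
                positions[i] = positions[i] + step
                # reflect off the walls
                x, y = positions[i]
                if x < margin or x > w - margin:
                    headings[i] = np.pi - headings[i]
                    positions[i][0] = np.clip(x, margin, w - margin)
                if y < margin or y > h - margin:
                    headings[i] = -headings[i]
                    positions[i][1] = np.clip(y, margin, h - margin)
            b_px = sched["b_axis"][f]
            rr, cc = _render_agent(
                canvas,
                positions[i],
                headings[i],
                a_px,
                b_px,
                leg_px,
                prob_px,
                config.agent_level,
            )
            records.append(
                (
                    f,
                    i,
                    float(cc.mean()),
                    float(rr.mean()),
                    beh,
                    float(np.pi * config.body_axes[0] * (b_px / cal.px_per_mm)),
                )
            )
        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)
        frames[f] = np.clip(canvas, 0, 255).astype(np.uint8)

    gt = GroundTruth(
        records=pd.DataFrame(
            records,
            columns=["frame", "agent_id", "x_px", "y_px", "behavior", "area_mm2"],
        ),
        engorged=engorged,
        engorgement_time=engorge_time,
    )
    return frames, gt


def generate_area_series(
    baseline: float,
    profile="none",
    duration: float = 100.0,
    fps: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AreaSeries:
    """Synthetic abdominal-area series (mm²).

    ``profile`` is "none" (constant baseline), ("step", t0, plateau)
    (jump at t0), or ("ramp", t0, t1, plateau) (linear rise between t0 and
    t1). Gaussian noise of sd ``noise_sd`` is added; values are clipped to
    stay positive.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    if profile == "none" or profile == ("none",):
        values = np.full(n, float(baseline))
    elif isinstance(profile, tuple) and profile[0] == "step":
        _, t0, plateau = profile
        if plateau < baseline:
            raise ValueError("feeding plateau must be >= baseline")
        values = np.where(t < t0, baseline, plateau)
    elif isinstance(profile, tuple) and profile[0] == "ramp":
        _, t0, t1, plateau = profile
        if plateau < baseline:
            raise ValueError("feeding plateau must be >= baseline")
        if t1 <= t0:
            raise ValueError("ramp needs t1 > t0")
        values = np.interp(t, [t0, t1], [baseline, plateau])
    else:
        raise ValueError(f"unknown profile {profile!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=n)
    values = np.maximum(values, 1e-6)
    return AreaSeries(fps=fps, values=values)


# resting egocentric layout, mm: +x anterior from the abdominal tip
_POSE_REST = {
    "abdomen_tip": (0.0, 0.0),
    "abdomen_center": (1.5, 0.0),
    "head": (3.2, 0.0),
    "proboscis_tip": (4.5, 0.0),
    "leg_R1": (3.0, -1.5),
    "leg_R2": (2.0, -1.8),
    "leg_R3": (0.8, -1.6),
    "leg_L1": (3.0, 1.5),
    "leg_L2": (2.0, 1.8),
    "leg_L3": (0.8, 1.6),
}

POSE_BEHAVIORS = ("grooming", "walking", "probing")


def generate_pose_sequence(
    behavior: str,
    duration: float = 4.0,
    fps: float = 25.0,
    seed: int = 0,
    frequency: float = 3.0,
    calibration: Calibration | None = None,
) -> PoseTrack:
    """Synthetic body-part track with the qualitative signature of one
    behavior, embedded in image coordinates with a random pose.

    grooming: forelegs trace circles while the middle legs stay put;
    walking: all leg x-coordinates oscillate along the body axis at
    ``frequency`` Hz (tripod phases) while the body translates;
    probing: fore and middle legs pull toward the body in fast jerks.
    All likelihoods are 1.0.
    """
    if behavior not in POSE_BEHAVIORS:
        raise ValueError(f"unknown behavior {behavior!r}; expected {POSE_BEHAVIORS}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    cal = calibration or Calibration(um_per_px=25.0, fps=fps)
    rng = np.random.default_rng(seed)
    n = int(round(duration * fps))
    t = np.arange(n) / fps

    ego = {p: np.tile(np.asarray(xy, float), (n, 1)) for p, xy in _POSE_REST.items()}
    if behavior == "grooming":
        f_groom = 2.0
        for k, leg in enumerate(("leg_R1", "leg_L1")):
            phase = np.pi * k
            ego[leg] = ego[leg] + 0.4 * np.column_stack(
                [np.cos(2 * np.pi * f_groom * t + phase), np.sin(2 * np.pi * f_groom * t + phase)]
            )
        ego["proboscis_tip"] = ego["proboscis_tip"] + 0.2 * np.column_stack(
            [np.cos(2 * np.pi * f_groom * t - 0.5), np.sin(2 * np.pi * f_groom * t - 0.5)]
        )
    elif behavior == "walking":
        tripod = {"leg_R1": 0, "leg_L2": 0, "leg_R3": 0, "leg_L1": 1, "leg_R2": 1, "leg_L3": 1}
        for leg, grp in tripod.items():
            ego[leg][:, 0] += 0.5 * np.sin(2 * np.pi * frequency * t + grp * np.pi)
    else:  # probing
        period = 1.0 / max(frequency, 1.0)
        phase = (t % period) / period
        jerk = np.exp(-phase / 0.15)  # sharp attack, fast decay
        for leg in ("leg_R1", "leg_L1", "leg_R2", "leg_L2"):
            toward = np.asarray(_POSE_REST["abdomen_center"]) - np.asarray(_POSE_REST[leg])
            toward = toward / np.linalg.norm(toward)
            ego[leg] = ego[leg] + 0.6 * jerk[:, None] * toward[None, :]

    # embed in image coordinates: random heading/origin, optional drift
    theta = rng.uniform(0, 2 * np.pi)
    origin = rng.uniform(200, 300, size=2)
    drift = np.zeros((n, 2))
    if behavior == "walking":
        v_px = cal.mm_to_px(5.0) / fps
        drift = np.outer(np.arange(n), v_px * np.array([np.cos(theta), np.sin(theta)]))
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    coords = {}
    for part, xy_mm in ego.items():
        xy_px = cal.mm_to_px(xy_mm) @ rot.T + origin + drift
        coords[part] = xy_px
    labels = np.full(n, behavior, dtype=object)
    return PoseTrack.from_arrays(coords, fps=fps, labels=labels)
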