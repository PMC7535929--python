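"""Region-of-interest analytics for surface repellency assays.

Quantifies how mosquitoes interact with an arbitrary polygonal region of
the substrate (e.g. a repellent-coated patch): landing rates normalized by
area, mean dwell times with proportional splitting across regions,
touch-and-go detection (landing followed by take-off within a residence
cutoff), and per-appendage contact events from pose tracks.

Boundary convention: a point exactly on a polygon edge counts as inside —
contacts at the coated edge are the scientifically interesting case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely

from .calibration import Calibration


@dataclass
class ROI:
    """Named simple polygon on the substrate, vertices in pixels."""

    name: str
    vertices: np.ndarray  # (n, 2) px

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValueError("polygon needs at least 3 vertices")
        self._poly = shapely.Polygon(self.vertices)
        if not self._poly.is_valid or self._poly.area <= 0:
            raise ValueError(f"degenerate or self-intersecting polygon {self.name!r}")

    @property
    def area_px2(self) -> float:
        return float(self._poly.area)

    def area_mm2(self, calibration: Calibration) -> float:
        return float(calibration.px2_to_mm2(self._poly.area))

    def contains(self, xy) -> np.ndarray:
        """Boundary-inclusive membership test for (n, 2) points."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return shapely.covers(self._poly, shapely.points(xy))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "vertices": self.vertices.tolist(), "units": "px"},
                fh,
            )

    @classmethod
    def from_json(cls, path, calibration: Calibration | None = None) -> "ROI":
        with open(path) as fh:
            d = json.load(fh)
        verts = np.asarray(d["vertices"], dtype=float)
        if d.get("units", "px") == "mm":
            if calibration is None:
                raise ValueError("mm-unit ROI requires a calibration")
            verts = calibration.mm_to_px(verts)
        return cls(name=d["name"], vertices=verts)

    @classmethod
    def from_mask(cls, mask, name: str = "roi") -> "ROI":
        """Polygonize the largest contour of a binary mask image."""
        from skimage.measure import find_contours

        contours = find_contours(np.asarray(mask, dtype=float), 0.5)
        if not contours:
            raise ValueError("empty ROI mask")
        boundary = max(contours, key=len)[:, ::-1]  # (x, y)
        step = max(1, len(boundary) // 200)
        return cls(name=name, vertices=boundary[::step])


@dataclass
class ContactEvent:
    """One maximal run of frames during which a body part is inside a ROI."""

    individual: object
    part: str
    entry_s: float
    exit_s: float

    def __post_init__(self) -> None:
        if self.exit_s < self.entry_s:
            raise ValueError("exit must not precede entry")


def landing_rate(trajectories, roi: ROI, calibration: Calibration) -> float:
    """Trajectories whose first sample lies inside the polygon, per mm²."""
    if not trajectories:
        return 0.0
    starts = np.array([t.xy[0] for t in trajectories], dtype=float)
    return float(roi.contains(starts).sum() / roi.area_mm2(calibration))


def dwell_times(trajectories, rois, fps: float) -> dict[str, float]:
    """Mean dwell time (s) per ROI.

    Each trajectory contributes to each region the summed time its
    centroid spends inside, so an episode spanning two surfaces is split
    proportionally to the time spent on each. The mean is over the
    trajectories that contribute a positive time to that region.
    """
    contributions: dict[str, list[float]] = {r.name: [] for r in rois}
    for traj in trajectories:
        for roi in rois:
            t_in = roi.contains(traj.xy).sum() / fps
            if t_in > 0:
                contributions[roi.name].append(float(t_in))
    return {
        name: (float(np.mean(vals)) if vals else 0.0)
        for name, vals in contributions.items()
    }


def detect_touch_and_go(
    trajectory, roi: ROI, fps: float | None = None, max_residence_s: float = 0.5
) -> bool:
    """Landing inside the ROI followed by immediate take-off.

    True iff the trajectory's first sample is inside the polygon and the
    total residence time in it is strictly below ``max_residence_s``.
    A trajectory that lands outside and walks on is not touch-and-go.
    """
    fps = fps if fps is not None else trajectory.fps
    inside = roi.contains(trajectory.xy)
    if not inside[0]:
        return False
    return bool(inside.sum() / fps < max_residence_s)


def _bridge_gaps(inside: np.ndarray, bridge: int) -> np.ndarray:
    """Fill short False runs flanked by True (tracking jitter)."""
    if bridge <= 0 or len(inside) == 0:
        return inside
    out = inside.copy()
    n = len(out)
    i = 0
    while i < n:
        if not out[i]:
            j = i
            while j < n and not out[j]:
                j += 1
            if i > 0 and j < n and (j - i) <= bridge:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def score_body_part_contacts(
    pose_track,
    roi: ROI,
    min_likelihood: float = 0.9,
    parts=None,
    individual=0,
    bridge_gap: int = 1,
) -> list[ContactEvent]:
    """Per-appendage contact events with a region.

    For each tracked part, point-in-polygon is evaluated on every frame
    whose likelihood reaches ``min_likelihood``; maximal runs of inside
    frames become ContactEvents. Single-frame dropouts inside a run are
    bridged (``bridge_gap``).
    """
    available = pose_track.parts
    parts = list(parts) if parts is not None else available
    missing = [p for p in parts if p not in available]
    if missing:
        raise ValueError(f"body parts absent from table: {missing}")
    fps = pose_track.fps
    events = []
    for part in parts:
        valid = pose_track.likelihood(part) >= min_likelihood
        inside = roi.contains(pose_track.xy(part)) & valid
        inside = _bridge_gaps(inside, bridge_gap)
        d = np.diff(np.concatenate([[0], inside.astype(int), [0]]))
        starts = np.nonzero(d == 1)[0]
        ends = np.nonzero(d == -1)[0] - 1
        for s, e in zip(starts, ends):
            events.append(
                ContactEvent(
                    individual=individual,
                    part=part,
                    entry_s=float(s / fps),
                    exit_s=float(e / fps),
                )
            )
    return events


def contact_ethogram(
    events: list[ContactEvent], presence: tuple[float, float]
) -> dict[str, list[tuple[float, float]]]:
    """Timeline lanes: one "presence" lane spanning the episode plus one
    lane per appendage with its contact intervals. Events outside the
    presence interval are rejected."""
    t0, t1 = presence
    lanes: dict[str, list[tuple[float, float]]] = {"presence": [(t0, t1)]}
    for ev in sorted(events, key=lambda e: (e.part, e.entry_s)):
        if ev.entry_s < t0 - 1e-9 or ev.exit_s > t1 + 1e-9:
            raise ValueError(
                f"contact event [{ev.entry_s}, {ev.exit_s}] outside presence [{t0}, {t1}]"
            )
        lanes.setdefault(ev.part, []).append((ev.entry_s, ev.exit_s))
    return lanes
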