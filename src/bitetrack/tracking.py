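"""Detection of mosquito bodies and identity-preserving tracking.

Detection follows the classic pipeline for dark animals on a bright,
back-lit substrate: a temporal-median background is subtracted, the
absolute difference image is thresholded (Otsu by default), cleaned up by
morphological opening and closing, and connected components within a
plausible body-area range become detections with intensity-weighted
centroids.

Linking follows the Crocker–Grier scheme: per frame, candidate
(track, detection) pairs within a search radius are assigned one-to-one so
that the total squared displacement is minimal; tracks missing a detection
persist for a configurable number of memory frames before they are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import closing, disk, opening

from .calibration import Calibration

_FORBIDDEN = 1e12  # cost for pairs outside the search radius


@dataclass(frozen=True)
class Detection:
    """One segmented mosquito body in one frame.

    Coordinates are image pixels: origin top-left, x to the right, y down.
    ``bbox`` is half-open ``(x0, y0, x1, y1)``.
    """

    frame: int
    centroid: tuple[float, float]
    area: float  # px^2
    bbox: tuple[int, int, int, int]


@dataclass
class Track:
    """Time-ordered centroid samples of one individual."""

    track_id: int
    frames: np.ndarray  # (n,), strictly increasing
    xy: np.ndarray  # (n, 2) px
    areas: np.ndarray  # (n,) px^2

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """Frame intervals (exclusive ends) bridged by linker memory."""
        out = []
        d = np.diff(self.frames)
        for i in np.nonzero(d > 1)[0]:
            out.append((int(self.frames[i]) + 1, int(self.frames[i + 1])))
        return out


@dataclass
class Trajectory:
    """One landing-to-departure episode: a contiguous slice of a Track.

    Behavior labels and the engorgement result are attached downstream by
    the behavior and bodyshape modules.
    """

    track_id: int
    start_frame: int
    end_frame: int
    frames: np.ndarray
    xy: np.ndarray
    areas: np.ndarray
    fps: float
    labels: np.ndarray | None = None
    engorgement: object | None = None

    @property
    def duration(self) -> float:
        return (self.end_frame - self.start_frame + 1) / self.fps

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class LinkParams:
    """Detection and linking parameters.

    search_range is the maximal per-frame displacement in mm; blob area
    limits are in mm² and converted to px² via the calibration.
    threshold_method is "otsu" or ("fixed", level).
    """

    search_range: float = 2.0  # mm / frame
    memory: int = 3  # frames a lost particle is kept alive
    min_blob_area: float = 0.5  # mm^2
    max_blob_area: float = 20.0  # mm^2
    threshold_method: object = "otsu"

    def __post_init__(self) -> None:
        if self.search_range <= 0:
            raise ValueError("search_range must be positive")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


def estimate_background(frames, stride: int = 1) -> np.ndarray:
    """Per-pixel temporal median over frames sampled every ``stride``.

    Robust to moving agents as long as each pixel is background in more
    than half of the sampled frames.
    """
    frames = np.asarray(frames)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    sampled = frames[::stride]
    if len(sampled) < 3:
        raise ValueError(
            f"need at least 3 sampled frames for a background, got {len(sampled)}"
        )
    return np.median(sampled.astype(float), axis=0)


def detect_mosquitoes(
    frame,
    background,
    params: LinkParams,
    calibration: Calibration,
    frame_index: int = 0,
    morph_radius: int = 2,
) -> list[Detection]:
    """Segment mosquito bodies in one frame.

    |frame − background| is thresholded, opened then closed with a disk of
    ``morph_radius`` px, and connected components with area inside
    [min_blob_area, max_blob_area] (mm² → px²) are returned with
    intensity-weighted centroids.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = np.abs(frame - background)
    if diff.max() <= 1e-9:
        return []
    if params.threshold_method == "otsu":
        level = threshold_otsu(diff)
    elif (
        isinstance(params.threshold_method, tuple)
        and params.threshold_method[0] == "fixed"
    ):
        level = float(params.threshold_method[1])
    else:
        raise ValueError(f"unknown threshold_method {params.threshold_method!r}")
    mask = diff > level
    if morph_radius > 0:
        selem = disk(morph_radius)
        mask = closing(opening(mask, selem), selem)
    if not mask.any():
        return []
    min_px = calibration.mm2_to_px2(params.min_blob_area)
    max_px = calibration.mm2_to_px2(params.max_blob_area)
    detections = []
    for region in regionprops(cc_label(mask), intensity_image=diff):
        if not (min_px <= region.area <= max_px):
            continue
        cy, cx = region.centroid_weighted
        r0, c0, r1, c1 = region.bbox
        detections.append(
            Detection(
                frame=frame_index,
                centroid=(float(cx), float(cy)),
                area=float(region.area),
                bbox=(int(c0), int(r0), int(c1), int(r1)),
            )
        )
    return detections


def _assign(prev_xy: np.ndarray, new_xy: np.ndarray, r_px: float):
    """Optimal one-to-one assignment minimizing total squared displacement.

    Augmented square cost matrix: linking costs the squared distance (only
    within the search radius); leaving either side unmatched costs r².
    Returns a list of (prev_index, new_index) links.
    """
    t, d = len(prev_xy), len(new_xy)
    if t == 0 or d == 0:
        return []
    sq = ((prev_xy[:, None, :] - new_xy[None, :, :]) ** 2).sum(axis=2)
    r2 = r_px**2
    cost = np.full((t + d, d + t), _FORBIDDEN)
    link = np.where(sq <= r2, sq, _FORBIDDEN)
    cost[:t, :d] = link
    cost[:t, d:] = np.where(np.eye(t, dtype=bool), r2, _FORBIDDEN)
    cost[t:, :d] = np.where(np.eye(d, dtype=bool), r2, _FORBIDDEN).reshape(d, d)
    cost[t:, d:] = 0.0
    rows, cols = linear_sum_assignment(cost)
    return [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < t and j < d and cost[i, j] < _FORBIDDEN
    ]


def link_detections(
    detections_by_frame,
    params: LinkParams,
    calibration: Calibration,
    fps: float | None = None,
) -> list[Track]:
    """Link per-frame detections into identity-preserved tracks.

    ``detections_by_frame`` maps frame index → list of Detection (a list of
    lists indexed by frame also works). Unmatched tracks persist for up to
    ``params.memory`` frames; reappearance within the search radius resumes
    the same track id.
    """
    if isinstance(detections_by_frame, dict):
        items = sorted(detections_by_frame.items())
    else:
        items = list(enumerate(detections_by_frame))
    r_px = calibration.mm_to_px(params.search_range)

    next_id = 0
    active: list[dict] = []
    closed: list[dict] = []

    for frame, dets in items:
        still = []
        for tr in active:
            if frame - tr["last_frame"] - 1 > params.memory:
                closed.append(tr)
            else:
                still.append(tr)
        active = still
        if not dets:
            continue
        new_xy = np.array([d.centroid for d in dets], dtype=float)
        prev_xy = np.array([tr["last_xy"] for tr in active], dtype=float).reshape(
            -1, 2
        )
        links = _assign(prev_xy, new_xy, r_px)
        matched_new = set()
        for i, j in links:
            tr = active[i]
            tr["samples"].append((frame, dets[j].centroid, dets[j].area))
            tr["last_xy"] = dets[j].centroid
            tr["last_frame"] = frame
            matched_new.add(j)
        for j, det in enumerate(dets):
            if j in matched_new:
                continue
            active.append(
                {
                    "id": next_id,
                    "samples": [(frame, det.centroid, det.area)],
                    "last_xy": det.centroid,
                    "last_frame": frame,
                }
            )
            next_id += 1

    tracks = []
    for tr in sorted(closed + active, key=lambda t: t["id"]):
        frames = np.array([s[0] for s in tr["samples"]], dtype=int)
        xy = np.array([s[1] for s in tr["samples"]], dtype=float)
        areas = np.array([s[2] for s in tr["samples"]], dtype=float)
        tracks.append(Track(tr["id"], frames, xy, areas))
    return tracks


def segment_trajectories(track: Track, fps: float, gap_s: float = 1.0) -> list[Trajectory]:
    """Split a track at detection gaps longer than ``gap_s`` seconds.

    Such a gap is interpreted as a departure followed by a re-landing; each
    piece becomes one Trajectory.
    """
    if len(track) == 0:
        raise ValueError("track is empty")
    max_gap = gap_s * fps
    breaks = np.nonzero(np.diff(track.frames) - 1 > max_gap)[0]
    pieces = np.split(np.arange(len(track)), breaks + 1)
    out = []
    for idx in pieces:
        out.append(
            Trajectory(
                track_id=track.track_id,
                start_frame=int(track.frames[idx[0]]),
                end_frame=int(track.frames[idx[-1]]),
                frames=track.frames[idx],
                xy=track.xy[idx],
                areas=track.areas[idx],
                fps=fps,
            )
        )
    return out


def crop_sequences(frames, trajectory: Trajectory, box_size: int = 128) -> np.ndarray:
    """Per-frame crops centered on the focal mosquito, zero-padded at borders.

    Returns an array of shape (len(trajectory), box_size, box_size).
    """
    if box_size % 2 != 0:
        raise ValueError("box_size must be even")
    if len(trajectory) == 0:
        raise ValueError("trajectory is empty")
    frames = np.asarray(frames)
    if trajectory.frames.max() >= len(frames):
        raise ValueError("trajectory extends past the frame stack")
    half = box_size // 2
    crops = np.zeros((len(trajectory), box_size, box_size), dtype=frames.dtype)
    h, w = frames.shape[1:3]
    for k, (f, (x, y)) in enumerate(zip(trajectory.frames, trajectory.xy)):
        cx, cy = int(round(x)), int(round(y))
        y0, y1 = cy - half, cy + half
        x0, x1 = cx - half, cx + half
        sy0, sy1 = max(y0, 0), min(y1, h)
        sx0, sx1 = max(x0, 0), min(x1, w)
        crops[k, sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = frames[
            f, sy0:sy1, sx0:sx1
        ]
    return crops


def evaluate_tracking(
    tracks: list[Track], ground_truth: pd.DataFrame, match_radius_px: float = 10.0
) -> dict:
    """Score tracks against ground-truth identities from synthetic scenes.

    Each track sample is matched to the nearest ground-truth agent in the
    same frame within ``match_radius_px``. A track counts as one error if
    its matched identity is not unique along the track (an identity swap or
    a merge of two agents). Returns n_tracks_checked, n_errors, error_rate.
    """
    by_frame = {
        f: g[["agent_id", "x_px", "y_px"]].to_numpy()
        for f, g in ground_truth.groupby("frame")
    }
    n_checked = 0
    n_errors = 0
    for track in tracks:
        ids = []
        for f, (x, y) in zip(track.frames, track.xy):
            g = by_frame.get(int(f))
            if g is None or len(g) == 0:
                continue
            d = np.hypot(g[:, 1] - x, g[:, 2] - y)
            k = int(np.argmin(d))
            if d[k] <= match_radius_px:
                ids.append(int(g[k, 0]))
        if not ids:
            continue
        n_checked += 1
        if len(set(ids)) > 1:
            n_errors += 1
    if n_checked == 0:
        raise ValueError("no overlap between tracks and ground truth")
    return {
        "n_tracks_checked": n_checked,
        "n_errors": n_errors,
        "error_rate": n_errors / n_checked,
    }


def relabel_tracks(tracks: list[Track], mapping: dict[int, int]) -> list[Track]:
    """Apply manual identity corrections (old id → new id), merging tracks.

    Stands in for interactive editing of identity swaps: corrections are
    recorded in an edit table and applied in one pass. Samples of merged
    tracks are concatenated in frame order.
    """
    groups: dict[int, list[Track]] = {}
    for t in tracks:
        groups.setdefault(mapping.get(t.track_id, t.track_id), []).append(t)
    out = []
    for new_id, members in sorted(groups.items()):
        frames = np.concatenate([m.frames for m in members])
        xy = np.concatenate([m.xy for m in members])
        areas = np.concatenate([m.areas for m in members])
        order = np.argsort(frames, kind="stable")
        out.append(Track(new_id, frames[order], xy[order], areas[order]))
    return out


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table: frame, track_id, x_px, y_px, area_px2."""
    rows = []
    for t in tracks:
        for f, (x, y), a in zip(t.frames, t.xy, t.areas):
            rows.append((int(f), t.track_id, float(x), float(y), float(a)))
    return pd.DataFrame(
        rows, columns=["frame", "track_id", "x_px", "y_px", "area_px2"]
    ).sort_values(["frame", "track_id"], ignore_index=True)


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    out = []
    for tid, g in df.groupby("track_id"):
        g = g.sort_values("frame")
        out.append(
            Track(
                int(tid),
                g["frame"].to_numpy(int),
                g[["x_px", "y_px"]].to_numpy(float),
                g.get("area_px2", pd.Series(np.zeros(len(g)))).to_numpy(float),
            )
        )
    return out


def render_overlay(frames, tracks: list[Track]) -> np.ndarray:
    """Validation overlay: marks each track's centroid with an id-specific
    grey-level square so identities can be checked visually frame by frame."""
    frames = np.asarray(frames)
    out = frames.copy()
    for t in tracks:
        level = 255 - (t.track_id * 37) % 128
        for f, (x, y) in zip(t.frames, t.xy):
            cx, cy = int(round(x)), int(round(y))
            y0, y1 = max(cy - 2, 0), min(cy + 3, frames.shape[1])
            x0, x1 = max(cx - 2, 0), min(cx + 3, frames.shape[2])
            out[f, y0:y1, x0:x1] = level
    return out
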