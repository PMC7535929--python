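"""Detection, Crocker–Grier linking, trajectory segmentation, cropping,
and tracking validation against synthetic ground truth."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bitetrack.calibration import Calibration
from bitetrack.synth import SceneConfig, generate_scene
from bitetrack.tracking import (
    Detection,
    LinkParams,
    Track,
    Trajectory,
    crop_sequences,
    detect_mosquitoes,
    estimate_background,
    evaluate_tracking,
    link_detections,
    relabel_tracks,
    segment_trajectories,
    tracks_to_dataframe,
)

# 1 px = 1 mm: distances in linking tests read directly in pixels
CAL_UNIT = Calibration(um_per_px=1000.0)


def _det(frame, x, y, area=100.0):
    return Detection(frame, (float(x), float(y)), area, (0, 0, 1, 1))


class TestBackground:
    def test_identical_frames(self):
        frames = np.full((5, 10, 10), 37.0)
        assert np.array_equal(estimate_background(frames), frames[0])

    def test_moving_blob_median_oracle(self):
        frames = np.full((9, 20, 20), 100.0)
        for i in range(9):
            frames[i, 5:8, 2 * i : 2 * i + 2] = 10.0  # small blob sweeping right
        bg = estimate_background(frames, stride=1)
        oracle = np.median(frames, axis=0)
        assert np.array_equal(bg, oracle)
        assert np.all(bg == 100.0)

    def test_stride_samples_every_kth_frame(self):
        frames = np.arange(10, dtype=float)[:, None, None] * np.ones((10, 2, 2))
        bg = estimate_background(frames, stride=2)  # frames 0,2,4,6,8
        assert np.all(bg == 4.0)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            estimate_background(np.zeros((2, 4, 4)))
        with pytest.raises(ValueError):
            estimate_background(np.zeros((8, 4, 4)), stride=4)


class TestDetect:
    def test_frame_equal_background_gives_nothing(self, cal):
        frame = np.full((50, 50), 120.0)
        assert detect_mosquitoes(frame, frame, LinkParams(), cal) == []

    def test_ellipse_centroid_subpixel(self, cal):
        bg = np.full((120, 120), 200.0)
        frame = bg.copy()
        cx, cy = 60.3, 55.7
        ys, xs = np.mgrid[0:120, 0:120]
        inside = ((xs - cx) / 30) ** 2 + ((ys - cy) / 12) ** 2 <= 1
        frame[inside] = 60.0
        dets = detect_mosquitoes(frame, bg, LinkParams(), cal)
        assert len(dets) == 1
        assert abs(dets[0].centroid[0] - cx) < 0.5
        assert abs(dets[0].centroid[1] - cy) < 0.5
        x0, y0, x1, y1 = dets[0].bbox
        assert x0 <= cx < x1 and y0 <= cy < y1

    def test_small_blob_filtered(self, cal):
        bg = np.full((60, 60), 200.0)
        frame = bg.copy()
        frame[30:36, 30:36] = 60.0  # 36 px² << min_blob_area
        assert detect_mosquitoes(frame, bg, LinkParams(), cal) == []

    def test_shape_mismatch_rejected(self, cal):
        with pytest.raises(ValueError):
            detect_mosquitoes(np.zeros((5, 5)), np.zeros((6, 6)), LinkParams(), cal)


class TestLink:
    def test_stationary_detection_one_track(self):
        dets = {f: [_det(f, 3.0, 4.0)] for f in range(50)}
        tracks = link_detections(dets, LinkParams(), CAL_UNIT)
        assert len(tracks) == 1
        assert len(tracks[0]) == 50

    def test_nearest_assignment_beats_swap(self):
        """Two particles at (0,0), (10,0) moving to (1,0), (11,0): the
        optimal pairing has total squared displacement 2, the swap 162."""
        dets = {
            0: [_det(0, 0, 0), _det(0, 10, 0)],
            1: [_det(1, 1, 0), _det(1, 11, 0)],
        }
        tracks = link_detections(dets, LinkParams(search_range=20.0), CAL_UNIT)
        assert len(tracks) == 2
        cost = sum(((t.xy[1] - t.xy[0]) ** 2).sum() for t in tracks)
        assert cost == pytest.approx(2.0)

    def test_memory_bridges_gap_but_not_longer(self):
        p = LinkParams(search_range=2.0, memory=3)
        # absent frames 3,4,5 (= memory) then back
        dets = {f: [_det(f, 0, 0)] for f in [0, 1, 2, 6, 7]}
        tracks = link_detections(dets, p, CAL_UNIT)
        assert len(tracks) == 1 and tracks[0].gaps == [(3, 6)]
        # absent 4 frames (= memory + 1): the track is closed
        dets = {f: [_det(f, 0, 0)] for f in [0, 1, 2, 7, 8]}
        tracks = link_detections(dets, p, CAL_UNIT)
        assert len(tracks) == 2

    def test_empty_input(self):
        assert link_detections({}, LinkParams(), CAL_UNIT) == []

    @pytest.mark.parametrize("n_particles", [2, 3, 4, 5])
    def test_matches_brute_force_assignment(self, n_particles):
        """On two-frame problems the linker's total squared displacement
        equals the exhaustive minimum over all permutations."""
        rng = np.random.default_rng(n_particles)
        for _ in range(20):
            a = rng.uniform(0, 40, size=(n_particles, 2))
            b = a + rng.uniform(-3, 3, size=(n_particles, 2))
            dets = {
                0: [_det(0, *p) for p in a],
                1: [_det(1, *p) for p in b],
            }
            tracks = link_detections(dets, LinkParams(search_range=200.0), CAL_UNIT)
            assert len(tracks) == n_particles
            cost = sum(((t.xy[1] - t.xy[0]) ** 2).sum() for t in tracks)
            brute = min(
                sum(((a[i] - b[j]) ** 2).sum() for i, j in enumerate(perm))
                for perm in itertools.permutations(range(n_particles))
            )
            assert cost == pytest.approx(brute)

    def test_conservation_each_detection_in_one_track(self):
        rng = np.random.default_rng(0)
        dets = {
            f: [_det(f, *rng.uniform(0, 100, 2)) for _ in range(4)] for f in range(10)
        }
        tracks = link_detections(dets, LinkParams(search_range=500.0), CAL_UNIT)
        n_samples = sum(len(t) for t in tracks)
        assert n_samples == 40  # every detection used exactly once


class TestSegmentCrop:
    def _track(self, frames):
        frames = np.asarray(frames)
        return Track(0, frames, np.zeros((len(frames), 2)), np.zeros(len(frames)))

    def test_uninterrupted_track_single_trajectory(self):
        trajs = segment_trajectories(self._track(range(100)), fps=25.0, gap_s=1.0)
        assert len(trajs) == 1
        assert trajs[0].duration == pytest.approx(4.0)

    def test_long_gap_splits(self):
        # 3 s gap at 25 fps with gap_s = 1 → two landing episodes
        frames = list(range(50)) + list(range(125, 150))
        trajs = segment_trajectories(self._track(frames), fps=25.0, gap_s=1.0)
        assert len(trajs) == 2

    def test_presence_time_bookkeeping(self):
        frames = list(range(50)) + list(range(125, 150)) + list(range(300, 320))
        trajs = segment_trajectories(self._track(frames), fps=25.0, gap_s=1.0)
        spans = sum(t.end_frame - t.start_frame + 1 for t in trajs)
        assert spans == len(frames)  # contiguous pieces cover every detection
        assert sum(len(t) for t in trajs) == len(frames)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            segment_trajectories(self._track([]), fps=25.0)

    def test_crop_centered_and_padded(self):
        frames = np.zeros((3, 50, 50), dtype=np.uint8)
        frames[:, 20, 30] = 255
        traj = Trajectory(
            0, 0, 2, np.arange(3), np.tile([30.0, 20.0], (3, 1)), np.zeros(3), 25.0
        )
        crops = crop_sequences(frames, traj, box_size=16)
        assert crops.shape == (3, 16, 16)
        assert crops[0, 8, 8] == 255  # centroid at the crop center
        corner = Trajectory(
            0, 0, 0, np.arange(1), np.array([[1.0, 1.0]]), np.zeros(1), 25.0
        )
        c = crop_sequences(frames, corner, box_size=16)[0]
        assert c.shape == (16, 16)
        assert np.all(c[:7, :] == 0) and np.all(c[:, :7] == 0)  # zero padding

    def test_crop_validation(self):
        frames = np.zeros((3, 50, 50))
        traj = Trajectory(0, 0, 0, np.arange(1), np.zeros((1, 2)), np.zeros(1), 25.0)
        with pytest.raises(ValueError):
            crop_sequences(frames, traj, box_size=15)  # odd
        empty = Trajectory(0, 0, 0, np.empty(0, int), np.empty((0, 2)), np.empty(0), 25.0)
        with pytest.raises(ValueError):
            crop_sequences(frames, empty, box_size=16)


class TestEvaluate:
    @staticmethod
    def _truth(n_agents, n_frames=10, spacing=100.0):
        rows = [
            (f, i, spacing * i, 0.0)
            for f in range(n_frames)
            for i in range(n_agents)
        ]
        return pd.DataFrame(rows, columns=["frame", "agent_id", "x_px", "y_px"])

    @staticmethod
    def _track_for(truth, agent_id, track_id=0):
        g = truth[truth.agent_id == agent_id]
        return Track(
            track_id,
            g.frame.to_numpy(),
            g[["x_px", "y_px"]].to_numpy(float),
            np.zeros(len(g)),
        )

    def test_perfect_tracks_zero_errors(self):
        truth = self._truth(4)
        tracks = [self._track_for(truth, i, i) for i in range(4)]
        res = evaluate_tracking(tracks, truth)
        assert res == {"n_tracks_checked": 4, "n_errors": 0, "error_rate": 0.0}

    def test_five_errors_in_111_tracks(self):
        """An identity swap halfway through 5 of 111 tracks gives the
        0.045 validation error rate."""
        truth = self._truth(111)
        tracks = []
        for i in range(111):
            t = self._track_for(truth, i, i)
            if i < 5:  # splice in another agent's second half
                other = self._track_for(truth, (i + 50) % 111)
                t.xy[5:] = other.xy[5:]
            tracks.append(t)
        res = evaluate_tracking(tracks, truth)
        assert res["n_tracks_checked"] == 111
        assert res["n_errors"] == 5
        assert round(res["error_rate"], 3) == 0.045

    def test_constructed_swap_counts_once(self):
        truth = self._truth(2)
        swapped = self._track_for(truth, 0, 0)
        swapped.xy[5:] = self._track_for(truth, 1).xy[5:]
        clean = self._track_for(truth, 1, 1)
        res = evaluate_tracking([swapped, clean], truth)
        assert res["n_errors"] == 1

    def test_no_overlap_rejected(self):
        truth = self._truth(1)
        far = Track(0, np.arange(10), np.full((10, 2), 9999.0), np.zeros(10))
        with pytest.raises(ValueError):
            evaluate_tracking([far], truth)


class TestFullLoop:
    def test_crossing_free_scene_recovered_exactly(self, walking_scene):
        """Noise-free scene without crossings: the pipeline recovers the
        ground-truth track count with zero identity errors and sub-pixel
        centroids."""
        cfg, frames, gt = walking_scene
        cal = cfg.cal
        bg = estimate_background(frames, stride=5)
        dets = [
            detect_mosquitoes(f, bg, LinkParams(), cal, frame_index=i)
            for i, f in enumerate(frames)
        ]
        tracks = link_detections(dets, LinkParams(), cal, cfg.fps)
        assert len(tracks) == 2
        res = evaluate_tracking(tracks, gt.records)
        assert res["error_rate"] == 0.0
        by_frame = {
            (int(r.frame), int(r.agent_id)): (r.x_px, r.y_px)
            for r in gt.records.itertuples()
        }
        for t in tracks:
            errs = []
            for f, (x, y) in zip(t.frames, t.xy):
                d = min(
                    np.hypot(gx - x, gy - y)
                    for (fr, _), (gx, gy) in by_frame.items()
                    if fr == f
                )
                errs.append(d)
            assert max(errs) < 1.0

    def test_relabel_merges_tracks(self):
        a = Track(0, np.arange(5), np.zeros((5, 2)), np.zeros(5))
        b = Track(1, np.arange(5, 10), np.ones((5, 2)), np.zeros(5))
        merged = relabel_tracks([a, b], {1: 0})
        assert len(merged) == 1
        assert np.array_equal(merged[0].frames, np.arange(10))

    def test_tracks_table_round_trip(self):
        a = Track(3, np.arange(4), np.arange(8, dtype=float).reshape(4, 2), np.ones(4))
        df = tracks_to_dataframe([a])
        assert set(df.columns) == {"frame", "track_id", "x_px", "y_px", "area_px2"}
        assert len(df) == 4
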