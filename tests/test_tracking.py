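"""Linker correctness: oracle equivalence, memory, conservation, detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from spermscreen.synthetic import MotilityClassParams, PopulationConfig, render_frames, simulate_field
from spermscreen.tracking import (
    Detection,
    assign_frame,
    detect_spots,
    filter_tracks,
    link_detections,
)


def brute_force_cost(track_pos, det_pos, r):
    """Exhaustive minimum of the linking objective for one frame pair:
    sum of squared link displacements plus r^2 per unmatched track and
    per unmatched detection, links longer than r forbidden."""
    track_pos = np.asarray(track_pos, float).reshape(-1, 2)
    det_pos = np.asarray(det_pos, float).reshape(-1, 2)
    n_t, n_d = len(track_pos), len(det_pos)
    p = r * r
    if n_t == 0 or n_d == 0:
        return p * (n_t + n_d)
    d2 = ((track_pos[:, None, :] - det_pos[None, :, :]) ** 2).sum(-1)
    best = [p * (n_t + n_d)]

    def rec(i, used, delta):
        if i == n_t:
            best[0] = min(best[0], p * (n_t + n_d) + delta)
            return
        rec(i + 1, used, delta)
        for j in range(n_d):
            if j not in used and d2[i, j] <= p:
                rec(i + 1, used | {j}, delta + d2[i, j] - 2 * p)

    rec(0, frozenset(), 0.0)
    return best[0]


def realized_cost(track_pos, det_pos, r, links):
    track_pos = np.asarray(track_pos, float).reshape(-1, 2)
    det_pos = np.asarray(det_pos, float).reshape(-1, 2)
    lt, ld = links
    p = r * r
    d2 = ((track_pos[lt] - det_pos[ld]) ** 2).sum(-1)
    return float(d2.sum()) + p * (len(track_pos) - len(lt)) + p * (len(det_pos) - len(ld))


class TestAssignFrame:
    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n_t, n_d = rng.integers(0, 7, size=2)
            tp = rng.uniform(0, 25, size=(n_t, 2))
            dp = rng.uniform(0, 25, size=(n_d, 2))
            r = float(rng.uniform(3, 12))
            links = assign_frame(tp, dp, r)
            assert realized_cost(tp, dp, r, links) == pytest.approx(
                brute_force_cost(tp, dp, r), abs=1e-9
            )

    def test_no_link_longer_than_max_displacement(self):
        rng = np.random.default_rng(1)
        tp = rng.uniform(0, 30, size=(6, 2))
        dp = rng.uniform(0, 30, size=(6, 2))
        lt, ld = assign_frame(tp, dp, 5.0)
        if lt.size:
            assert np.all(np.hypot(*(tp[lt] - dp[ld]).T) <= 5.0 + 1e-12)

    def test_crossing_pair_resolved_optimally(self):
        # two tracks, two detections: the pairing minimizing total squared
        # displacement must win over the greedy nearest-neighbor choice
        tp = np.array([[0.0, 0.0], [10.0, 0.0]])
        dp = np.array([[4.0, 0.0], [11.0, 0.0]])
        lt, ld = assign_frame(tp, dp, 9.0)
        pairing = dict(zip(lt.tolist(), ld.tolist()))
        assert pairing == {0: 0, 1: 1}


class TestLinkDetections:
    @staticmethod
    def _table(points):
        return pd.DataFrame(points, columns=["frame", "x_um", "y_um"])

    def test_two_separated_straight_tracks(self):
        rows = []
        for f in range(10):
            rows.append((f, 2.0 * f, 0.0))
            rows.append((f, 2.0 * f, 100.0))
        linked = link_detections(self._table(rows), max_displacement=5.0)
        assert linked["track_id"].nunique() == 2
        per_y = linked.groupby("y_um")["track_id"].nunique()
        assert (per_y == 1).all()

    def test_memory_bridges_missing_frames(self):
        rows = [(f, 1.0 * f, 0.0) for f in (0, 1, 2, 5, 6)]  # gap of 2 frames
        linked = link_detections(self._table(rows), max_displacement=4.0, memory=2)
        assert linked["track_id"].nunique() == 1

    def test_gap_beyond_memory_splits_track(self):
        rows = [(f, 1.0 * f, 0.0) for f in (0, 1, 2, 6, 7)]  # gap of 3 frames
        linked = link_detections(self._table(rows), max_displacement=4.0, memory=2)
        assert linked["track_id"].nunique() == 2

    def test_every_detection_assigned_exactly_once(self):
        pop = PopulationConfig(n_cells=150, seed=21, detection_dropout_prob=0.05)
        f = simulate_field(pop)
        linked = link_detections(f.detections, max_displacement=15.0, memory=1)
        assert len(linked) == len(f.detections)
        assert (linked["track_id"] >= 0).all()
        # within a track, one detection per frame
        assert linked.groupby(["track_id", "frame"]).size().max() == 1

    def test_invalid_parameters_rejected(self):
        det = self._table([(0, 0.0, 0.0)])
        with pytest.raises(ValueError):
            link_detections(det, max_displacement=0.0)
        with pytest.raises(ValueError):
            link_detections(det, max_displacement=5.0, memory=-1)
        with pytest.raises(ValueError):
            link_detections(det.rename(columns={"x_um": "x"}), 5.0)

    def test_no_tracks_lost_without_dropout(self):
        pop = PopulationConfig(n_cells=100, seed=22, placement="grid",
                               detection_dropout_prob=0.0)
        f = simulate_field(pop)
        linked = link_detections(f.detections, max_displacement=15.0, memory=1)
        full = filter_tracks(linked, min_track_length=pop.n_frames)
        assert full["track_id"].nunique() >= 95  # dense PM crossings may swap a few


class TestFilterTracks:
    def test_identity_when_all_long_enough(self):
        df = pd.DataFrame({"track_id": [0, 0, 1, 1], "frame": [0, 1, 0, 1],
                           "x_um": 0.0, "y_um": 0.0})
        assert filter_tracks(df, 2).equals(df)

    def test_mixed_lengths(self):
        parts = []
        for tid, length in ((0, 2), (1, 5), (2, 50)):
            parts.append(pd.DataFrame({"track_id": tid, "frame": range(length),
                                       "x_um": 0.0, "y_um": 0.0}))
        df = pd.concat(parts, ignore_index=True)
        out = filter_tracks(df, 10)
        assert set(out["track_id"]) == {2}

    def test_min_length_validated(self):
        with pytest.raises(ValueError):
            filter_tracks(pd.DataFrame(columns=["track_id", "frame"]), 1)


class TestDetection:
    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            Detection(frame=0, x=float("nan"), y=0.0)
        with pytest.raises(ValueError):
            Detection(frame=-1, x=0.0, y=0.0)


class TestDetectSpots:
    def _render_points(self, points_um, pixel=1.0, sigma_um=2.0, amp=1000.0):
        pop = PopulationConfig(n_cells=len(points_um), n_frames=2,
                               field_size=(100.0, 80.0), seed=0)
        det = pd.DataFrame(
            [(0, x, y) for x, y in points_um], columns=["frame", "x_um", "y_um"]
        )
        f = simulate_field(pop)
        f.detections = det
        stack = render_frames(f, pixel_size_um=pixel, spot_sigma_um=sigma_um,
                              amplitude=amp, noise_sd=5.0, seed=3)
        return stack[0]

    def test_single_spot_round_trip_within_half_micron(self):
        img = self._render_points([(50.0, 30.0)])
        spots = detect_spots(img, spot_sigma=2.0, threshold=50.0)
        assert len(spots) == 1
        assert abs(spots["x_um"].iloc[0] - 50.0) < 0.5
        assert abs(spots["y_um"].iloc[0] - 30.0) < 0.5

    def test_blank_frame_yields_no_detections(self):
        assert len(detect_spots(np.zeros((64, 64)), 2.0, 10.0)) == 0

    def test_tiff_round_trip_preserves_detectability(self, tmp_path):
        from spermscreen.synthetic import load_frames_tiff, save_frames_tiff

        img = self._render_points([(50.0, 30.0)])
        path = tmp_path / "frames.tif"
        save_frames_tiff(img[None, ...], path)
        back = load_frames_tiff(path)
        frame = back if back.ndim == 2 else back[0]
        spots = detect_spots(frame, spot_sigma=2.0, threshold=50.0)
        assert len(spots) == 1
        assert abs(spots["x_um"].iloc[0] - 50.0) < 0.5

    def test_two_spots_separated_by_six_sigma(self):
        img = self._render_points([(30.0, 40.0), (44.0, 40.0)])  # 7 sigma apart
        spots = detect_spots(img, spot_sigma=2.0, threshold=50.0)
        assert len(spots) == 2
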