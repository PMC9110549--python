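"""Marker detection, Lucas-Kanade tracking and stability-interval logic."""
import numpy as np
import pytest

from ioct_hrfuse.errors import (
    ArrowNotFoundError,
    InvalidInputError,
    NoScanRegionError,
)
from ioct_hrfuse.tracking import (
    ScanPosition,
    ScanTrack,
    StabilityInterval,
    detect_arrow_points,
    detect_scan_rectangle,
    find_stable_intervals,
    track_feature,
)


class TestRectangleDetection:
    def test_corners_match_manifest(self, video_dir, scene_frames):
        _, manifest, _ = video_dir
        for t in (0, 10, 25):
            corners = detect_scan_rectangle(scene_frames[t])
            assert np.abs(corners - manifest.rect_corners(t)).max() < 1.0

    def test_black_frame_raises(self):
        with pytest.raises(NoScanRegionError):
            detect_scan_rectangle(np.zeros((120, 160, 3), dtype=np.uint8))

    def test_distractor_line_ignored(self, video_dir, scene_frames):
        _, manifest, _ = video_dir
        frame = scene_frames[3].copy()
        frame[200:202, 20:440] = 255  # bright distractor line
        corners = detect_scan_rectangle(frame)
        assert np.abs(corners - manifest.rect_corners(3)).max() < 1.0

    @pytest.mark.parametrize("scale", [0.8, 1.2])
    def test_brightness_scaling_invariance(self, video_dir, scene_frames, scale):
        _, manifest, _ = video_dir
        frame = np.clip(scene_frames[0].astype(float) * scale, 0, 255).astype(np.uint8)
        corners = detect_scan_rectangle(frame)
        assert np.abs(corners - manifest.rect_corners(0)).max() < 1.0


class TestArrowDetection:
    def test_points_match_manifest(self, video_dir, scene_frames):
        _, manifest, _ = video_dir
        for t in (0, 12):
            corners = detect_scan_rectangle(scene_frames[t])
            cyan, magenta = detect_arrow_points(scene_frames[t], corners)
            m_cyan, m_mag = manifest.arrow_points(t)
            assert np.hypot(*(cyan - m_cyan)) < 1.0
            assert np.hypot(*(magenta - m_mag)) < 1.0

    def test_missing_cyan_raises_named_error(self, video_dir, scene_frames):
        frame = scene_frames[0].copy()
        # repaint cyan pixels gray
        cy_mask = (frame[..., 0] < 80) & (frame[..., 1] > 200) & (frame[..., 2] > 200)
        frame[cy_mask] = 100
        corners = detect_scan_rectangle(frame)
        with pytest.raises(ArrowNotFoundError, match="cyan"):
            detect_arrow_points(frame, corners)

    @pytest.mark.parametrize("scale", [0.8, 1.2])
    def test_brightness_perturbation_tolerance(self, video_dir, scene_frames, scale):
        _, manifest, _ = video_dir
        frame = np.clip(scene_frames[0].astype(float) * scale, 0, 255).astype(np.uint8)
        corners = detect_scan_rectangle(frame)
        cyan, magenta = detect_arrow_points(frame, corners)
        m_cyan, m_mag = manifest.arrow_points(0)
        assert np.hypot(*(cyan - m_cyan)) < 2.0
        assert np.hypot(*(magenta - m_mag)) < 2.0


class TestFeatureTracking:
    def test_static_scene_no_drift(self, scene_frames, video_dir):
        _, manifest, _ = video_dir
        frames = [scene_frames[0]] * 20
        pts, status = track_feature(frames, tuple(manifest.feature_point(0)))
        assert status.all()
        drift = np.linalg.norm(pts[-1] - pts[0])
        assert drift < 0.1

    def test_moving_scene_follows_manifest(self, scene_frames, video_dir):
        _, manifest, _ = video_dir
        pts, status = track_feature(scene_frames, tuple(manifest.feature_point(0)))
        assert status.all()
        for t in range(len(scene_frames)):
            assert np.hypot(*(pts[t] - manifest.feature_point(t))) < 0.5

    def test_occlusion_marks_lost(self, scene_frames, video_dir):
        _, manifest, _ = video_dir
        frames = [f.copy() for f in scene_frames[:10]]
        occlude_from = 5
        for t in range(occlude_from, 10):
            x, y = manifest.feature_point(t).astype(int)
            frames[t][max(0, y - 15) : y + 15, max(0, x - 15) : x + 15] = 0
        pts, status = track_feature(frames, tuple(manifest.feature_point(0)))
        lost_at = np.nonzero(~status)[0]
        assert lost_at.size > 0 and lost_at[0] >= occlude_from
        # once lost, stays lost
        assert not status[lost_at[0] :].any()

    def test_empty_sequence_rejected(self):
        with pytest.raises(InvalidInputError):
            track_feature([], (5.0, 5.0))

    def test_seed_outside_frame_rejected(self):
        with pytest.raises(InvalidInputError):
            track_feature([np.zeros((50, 50))], (200.0, 5.0))


def _static_track(n, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    positions = []
    feature = np.zeros((n, 2))
    for i in range(n):
        eps = rng.uniform(-jitter, jitter, size=6) if jitter else np.zeros(6)
        positions.append(
            ScanPosition(
                rect_corners=np.array([[10, 10], [60, 10], [60, 40], [10, 40]], float),
                cyan_point=np.array([20.0, 25.0]) + eps[0:2],
                magenta_point=np.array([50.0, 25.0]) + eps[2:4],
                valid=True,
            )
        )
        feature[i] = np.array([100.0, 120.0]) + eps[4:6]
    return ScanTrack(positions, feature, np.ones(n, dtype=bool))


class TestStableIntervals:
    def test_fully_static_track_single_interval(self):
        track = _static_track(20)
        ivs = find_stable_intervals(track, min_len=8)
        assert [(iv.start_frame, iv.end_frame) for iv in ivs] == [(0, 19)]

    def test_short_segment_filtered_by_min_len(self):
        # stationary runs of 10 and 5 frames separated by a jump
        track = _static_track(20)
        for i in range(10, 15):  # displace frames 10..14 far away
            track.feature_points[i] += 50.0
        for i in range(15, 20):
            track.feature_points[i] += 100.0
        ivs = find_stable_intervals(track, min_len=8)
        assert [(iv.start_frame, iv.end_frame) for iv in ivs] == [(0, 9)]

    def test_empty_track_gives_empty_list(self):
        track = ScanTrack([], np.zeros((0, 2)), np.zeros(0, dtype=bool))
        assert find_stable_intervals(track, min_len=8) == []

    def test_invalid_frames_break_intervals(self):
        track = _static_track(20)
        track.positions[9] = ScanPosition.invalid()
        ivs = find_stable_intervals(track, min_len=8)
        assert [(iv.start_frame, iv.end_frame) for iv in ivs] == [(0, 8), (10, 19)]

    @pytest.mark.parametrize("seed", range(5))
    def test_intervals_disjoint_sorted_and_within_bounds(self, seed):
        """Re-assert each returned interval's deviation bounds from the track."""
        rng = np.random.default_rng(seed)
        track = _static_track(40, jitter=0.3, seed=seed)
        # random large jumps
        for i in rng.choice(40, size=5, replace=False):
            track.feature_points[i:] += rng.uniform(5, 20, 2)
        tol_step, tol_total = 1.5, 3.0
        ivs = find_stable_intervals(track, min_len=4, tol_step=tol_step, tol_total=tol_total)
        prev_end = -1
        for iv in ivs:
            assert iv.start_frame > prev_end
            prev_end = iv.end_frame
            assert iv.n_frames >= 4
            ref = track.state(iv.start_frame)
            for t in range(iv.start_frame, iv.end_frame + 1):
                assert np.abs(track.state(t) - ref).max() <= tol_total
                if t > iv.start_frame:
                    step = track.state(t) - track.state(t - 1)
                    assert np.abs(step).max() <= tol_step

    def test_track_json_roundtrip(self, tmp_path):
        track = _static_track(6, jitter=0.1, seed=3)
        track.positions[2] = ScanPosition.invalid()
        p = tmp_path / "track.json"
        track.save(p)
        back = ScanTrack.load(p)
        assert back.n_frames == track.n_frames
        assert np.allclose(back.feature_points, track.feature_points, equal_nan=True)
        assert back.positions[2].valid is False
        assert np.array_equal(back.positions[3].cyan_point, track.positions[3].cyan_point)

    def test_interval_roundtrip(self):
        iv = StabilityInterval(3, 14, 0.4, 0.2)
        assert StabilityInterval.from_dict(iv.to_dict()) == iv
        assert iv.n_frames == 12
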