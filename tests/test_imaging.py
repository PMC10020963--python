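"""Segmentation, feature extraction, classification, and state tracking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropxtal import (
    NEVER,
    ClassifierThresholds,
    DropletROI,
    FrameFeatures,
    classify_state,
    clear_fraction_curve,
    extract_features,
    segment_droplets,
    track_states,
)
from dropxtal.imaging import (
    CLEAR,
    CRYSTAL,
    DropletStateSeries,
    background_stats,
    calibrate_thresholds,
    read_state_table,
    write_state_table,
)
from dropxtal.synthetic import FrameStack


def _match_rois_to_truth(rois, truth, tol_px=5.0):
    """Greedy nearest-center matching; returns list of (droplet, roi) pairs."""
    pairs = []
    used = set()
    for d in truth:
        best, best_dist = None, tol_px
        for r in rois:
            if r.droplet_id in used:
                continue
            dist = math.hypot(
                r.center_px[0] - d.center_px[0], r.center_px[1] - d.center_px[1]
            )
            if dist < best_dist:
                best, best_dist = r, dist
        if best is not None:
            pairs.append((d, best))
            used.add(best.droplet_id)
    return pairs


class TestSegmentDroplets:
    def test_recovers_rendered_droplets(self, small_experiment):
        cfg, stack, truth = small_experiment
        rois = segment_droplets(stack.frames[0], 15, 40)
        assert len(rois) == len(truth)
        pairs = _match_rois_to_truth(rois, truth)
        assert len(pairs) == len(truth)
        for d, r in pairs:
            assert math.hypot(
                r.center_px[0] - d.center_px[0], r.center_px[1] - d.center_px[1]
            ) <= 2.0
            assert abs(r.radius_px - d.radius_px) <= 0.10 * d.radius_px

    def test_blank_noise_frame_yields_nothing(self):
        rng = np.random.default_rng(0)
        noise = 0.08 + rng.normal(0, 0.02, size=(400, 400))
        assert segment_droplets(noise, 15, 40) == []

    def test_constant_frame_yields_nothing(self):
        assert segment_droplets(np.full((200, 200), 0.5), 10, 30) == []

    def test_single_centered_droplet_radius(self):
        from dropxtal import EmulsionConfig, render_frame
        from dropxtal.synthetic import DropletGroundTruth

        cfg = EmulsionConfig(
            n_droplets=1, image_shape_px=(200, 200), droplet_radius_um=60.0, seed=5
        )
        drop = DropletGroundTruth(0, (100.0, 100.0), 30.0, 5e-4, NEVER)
        frame = render_frame([drop], 0.0, cfg)
        rois = segment_droplets(frame, 20, 45)
        assert len(rois) == 1
        assert 27 <= rois[0].radius_px <= 33

    def test_masks_disjoint_and_ids_sorted(self, small_experiment):
        _, stack, _ = small_experiment
        rois = segment_droplets(stack.frames[0], 15, 40)
        total = np.zeros(stack.frames[0].shape, dtype=int)
        for r in rois:
            total += r.mask
        assert total.max() <= 1
        keys = [r.center_px for r in rois]
        assert keys == sorted(keys)
        assert [r.droplet_id for r in rois] == list(range(len(rois)))

    def test_invalid_radius_bounds(self):
        with pytest.raises(ValueError):
            segment_droplets(np.zeros((50, 50)), 20, 10)


class TestExtractFeatures:
    def _roi(self, shape=(100, 100), center=(50.0, 50.0), radius=25.0):
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        mask = (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius**2
        return DropletROI(0, center, radius, mask)

    def test_uniform_frame_no_bright_area(self):
        roi = self._roi()
        frame = np.full((100, 100), 0.08)
        feats = extract_features(frame, roi, (0.08, 0.02))
        assert feats.bright_area_fraction == 0.0
        assert feats.max_intensity == pytest.approx(0.0)

    def test_crystal_covering_ten_percent_of_interior(self, nucleated_half_frame):
        # Rendered crystal blobs cover a known area; the measured bright
        # fraction must land in a sane band around the true coverage.
        cfg, population, frame = nucleated_half_frame
        bg = (0.08, cfg.noise_sd)
        for p in population[:5]:
            if p.nucleation_time_s > 600.0:
                continue
            roi = self._roi((700, 700), p.center_px, p.radius_px)
            feats = extract_features(frame, roi, bg)
            assert feats.bright_area_fraction > 0.02
            assert feats.max_intensity > 0.4

    def test_offset_invariance_with_recomputed_background(self):
        rng = np.random.default_rng(3)
        frame = 0.08 + rng.normal(0, 0.02, (100, 100))
        frame[45:55, 45:55] = 0.95
        roi = self._roi()
        f0 = extract_features(frame, roi, (0.08, 0.02))
        f1 = extract_features(frame + 0.17, roi, (0.25, 0.02))
        assert f1.max_intensity == pytest.approx(f0.max_intensity)
        assert f1.bright_area_fraction == pytest.approx(f0.bright_area_fraction)
        assert f1.gradient_energy == pytest.approx(f0.gradient_energy)

    def test_empty_interior_raises(self):
        rows = np.arange(20)[:, None]
        cols = np.arange(20)[None, :]
        tiny = (rows - 10) ** 2 + (cols - 10) ** 2 <= 1.0
        roi = DropletROI(0, (10.0, 10.0), 1.0, tiny)
        with pytest.raises(ValueError, match="empty interior"):
            extract_features(np.zeros((20, 20)), roi, (0.0, 1.0))


class TestClassifyState:
    def test_zero_features_clear(self):
        feats = FrameFeatures(0, 0.0, 0.0, 0.0)
        assert classify_state(feats) == CLEAR

    def test_saturating_intensity_crystal(self):
        feats = FrameFeatures(0, 0.9, 0.0, 0.0)
        assert classify_state(feats) == CRYSTAL

    @given(
        area=st.floats(0, 1),
        mx=st.floats(0, 1),
        th_lo=st.floats(0.001, 0.5),
        th_delta=st.floats(0.0, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_monotone(self, area, mx, th_lo, th_delta):
        # Raising the area threshold can only flip crystal → clear.
        feats = FrameFeatures(0, mx, area, 0.0)
        lo = classify_state(feats, ClassifierThresholds(area=th_lo, max_intensity=0.4))
        hi = classify_state(
            feats, ClassifierThresholds(area=th_lo + th_delta, max_intensity=0.4)
        )
        assert not (lo == CLEAR and hi == CRYSTAL)

    def test_calibration_separates_classes(self, small_experiment):
        cfg, stack, truth = small_experiment
        rois = segment_droplets(stack.frames[0], 15, 40)
        bg = background_stats(stack.frames[-1], rois)
        by_id = {d.droplet_id: d for d in truth}
        pairs = _match_rois_to_truth(rois, truth)
        clear_f, crystal_f = [], []
        t_last = stack.timestamps_s[-1]
        for d, r in pairs:
            feats = extract_features(stack.frames[-1], r, bg)
            (crystal_f if d.nucleation_time_s <= t_last - 60 else clear_f).append(feats)
        if not clear_f or not crystal_f:
            pytest.skip("fixture produced a single class")
        th = calibrate_thresholds(clear_f, crystal_f)
        calls = [classify_state(f, th) for f in crystal_f]
        assert calls.count(CRYSTAL) == len(crystal_f)
        calls = [classify_state(f, th) for f in clear_f]
        assert calls.count(CLEAR) == len(clear_f)


class TestTrackStates:
    def test_tracked_calls_match_ground_truth(self, small_experiment):
        cfg, stack, truth = small_experiment
        rois = segment_droplets(stack.frames[0], 15, 40)
        series = track_states(stack, rois)
        pairs = _match_rois_to_truth(rois, truth)
        by_roi = {s.droplet_id: s for s in series}
        errors = []
        for d, r in pairs:
            called = by_roi[r.droplet_id].first_crystal_time_s
            true_first_frame = (
                NEVER
                if d.nucleation_time_s > stack.timestamps_s[-1]
                else 60.0 * math.ceil(d.nucleation_time_s / 60.0)
            )
            if math.isinf(true_first_frame):
                assert math.isinf(called)
            else:
                errors.append(abs(called - true_first_frame))
        assert np.median(errors) <= 120.0  # within 2 frame intervals

    def test_monotone_states(self, small_experiment):
        _, stack, _ = small_experiment
        rois = segment_droplets(stack.frames[0], 15, 40)
        for s in track_states(stack, rois):
            crystal_seen = False
            for state in s.states:
                if state == CRYSTAL:
                    crystal_seen = True
                else:
                    assert not crystal_seen

    def test_debounce_ignores_single_frame_artifact(self):
        # Hand-built 3-frame stack: droplet bright only in the middle frame.
        shape = (80, 80)
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        mask = (rows - 40) ** 2 + (cols - 40) ** 2 <= 20**2
        frames = []
        for k in range(4):
            f = np.full(shape, 0.08)
            if k == 1:  # transient debris flash
                f[38:42, 38:42] = 0.95
            frames.append(f.astype(np.float32))
        stack = FrameStack(frames=frames, timestamps_s=np.arange(4) * 60.0)
        roi = DropletROI(0, (40.0, 40.0), 20.0, mask)
        (series,) = track_states(stack, [roi])
        assert series.states == [CLEAR] * 4
        assert math.isinf(series.first_crystal_time_s)

    def test_first_crystal_time_is_commit_frame(self):
        shape = (80, 80)
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        mask = (rows - 40) ** 2 + (cols - 40) ** 2 <= 20**2
        frames = []
        for k in range(5):
            f = np.full(shape, 0.08)
            if k >= 2:
                f[38:42, 38:42] = 0.95
            frames.append(f.astype(np.float32))
        stack = FrameStack(frames=frames, timestamps_s=np.arange(5) * 60.0)
        roi = DropletROI(0, (40.0, 40.0), 20.0, mask)
        (series,) = track_states(stack, [roi])
        assert series.first_crystal_time_s == 120.0
        assert series.states == [CLEAR, CLEAR, CRYSTAL, CRYSTAL, CRYSTAL]

    def test_shape_mismatch_raises(self, small_experiment):
        _, stack, _ = small_experiment
        rows = np.arange(10)[:, None]
        cols = np.arange(10)[None, :]
        mask = (rows - 5) ** 2 + (cols - 5) ** 2 <= 9
        roi = DropletROI(0, (5.0, 5.0), 3.0, mask)
        with pytest.raises(ValueError, match="shape"):
            track_states(stack, [roi])


class TestStateSeriesInvariants:
    def test_non_monotone_series_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            DropletStateSeries(
                droplet_id=0,
                timestamps_s=np.arange(3) * 60.0,
                states=[CLEAR, CRYSTAL, CLEAR],
                first_crystal_time_s=60.0,
            )

    def test_state_table_roundtrip(self, tmp_path):
        series = [
            DropletStateSeries(
                droplet_id=i,
                timestamps_s=np.arange(4) * 60.0,
                states=[CLEAR] * (i + 1) + [CRYSTAL] * (3 - i),
                first_crystal_time_s=(i + 1) * 60.0 if i < 3 else NEVER,
            )
            for i in range(4)
        ]
        write_state_table(series, tmp_path / "states.csv")
        back = read_state_table(tmp_path / "states.csv")
        assert len(back) == 4
        for a, b in zip(series, back):
            assert a.states == b.states
            assert a.first_crystal_time_s == b.first_crystal_time_s
        curve = clear_fraction_curve(back)
        np.testing.assert_allclose(curve.f_clear, [1.0, 0.75, 0.5, 0.25])
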