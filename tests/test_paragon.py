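"""Movement-index pipeline: variance, thresholding, counting, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from larvascreen import (
    AcquisitionSeries,
    FrameStack,
    ParagonParams,
    Rect,
    SimulationConfig,
    aggregate_replicates,
    build_grid,
    measure_plate,
    movement_index,
    normalize_index,
    select_frames,
    simulate_series,
    temporal_variance,
    threshold_motion,
)


class TestSelectFrames:
    def test_default_positions_pick_1_11_21(self, random_stack):
        sub = select_frames(random_stack)
        assert sub.n_frames == 3
        for out, pos in zip(sub.frames, (1, 11, 21)):
            np.testing.assert_array_equal(out, random_stack.frames[pos - 1])

    def test_identity_selection(self):
        stack = FrameStack(np.arange(3 * 4 * 4).reshape(3, 4, 4))
        sub = select_frames(stack, [1, 2, 3])
        np.testing.assert_array_equal(sub.frames, stack.frames)

    def test_out_of_range_position_named_in_error(self):
        stack = FrameStack(np.zeros((20, 4, 4)))
        with pytest.raises(IndexError, match="21"):
            select_frames(stack)

    def test_metadata_preserved(self, random_stack):
        random_stack.plate_id = "p7"
        random_stack.acquired_at_s = 300.0
        sub = select_frames(random_stack)
        assert sub.plate_id == "p7" and sub.acquired_at_s == 300.0


class TestTemporalVariance:
    @pytest.mark.parametrize(
        "trace, expected",
        [((5, 5, 5), 0.0), ((0, 3, 6), 6.0), ((1, 2, 3), 2.0 / 3.0)],
    )
    def test_population_variance_of_pixel_trace(self, trace, expected):
        frames = np.array(trace, dtype=float).reshape(-1, 1, 1)
        vmap = temporal_variance(FrameStack(frames))
        assert vmap.values[0, 0] == pytest.approx(expected)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            temporal_variance(FrameStack(np.zeros((1, 4, 4))))


class TestThresholdMotion:
    def test_uniform_map_all_zero(self):
        bmap = threshold_motion(np.full((10, 10), 3.7))
        assert bmap.values.sum() == 0

    def test_single_hot_pixel_among_99(self):
        # mean 1, std sqrt(99); cutoff ~30.85 -> exactly the hot pixel passes
        vmap = np.zeros((10, 10))
        vmap[3, 4] = 100.0
        bmap = threshold_motion(vmap)
        assert bmap.values.sum() == 1
        assert bmap.values[3, 4] == 1

    def test_single_pixel_map_zero(self):
        assert threshold_motion(np.array([[42.0]])).values.sum() == 0

    def test_strict_inequality_at_cutoff(self):
        # 10 pixels, nine 0 and one 100: mean 10, std 30, cutoff exactly 100;
        # the hot pixel equals the cutoff and must NOT fire (strict >)
        vmap = np.zeros((2, 5))
        vmap[0, 0] = 100.0
        assert vmap.mean() + 3 * vmap.std() == pytest.approx(100.0)
        assert threshold_motion(vmap).values.sum() == 0


class TestMovementIndex:
    def test_zero_map_any_region(self):
        region = np.zeros((8, 8), dtype=bool)
        region[2:5, 2:5] = True
        assert movement_index(np.zeros((8, 8), dtype=np.uint8), region) == 0

    def test_planted_pixels_counted_only_inside(self, rng):
        bmap = np.zeros((20, 20), dtype=np.uint8)
        region = np.zeros((20, 20), dtype=bool)
        region[:10, :10] = True
        inside = [(1, 2), (3, 4), (5, 6), (7, 8), (9, 9), (0, 0), (2, 9)]
        outside = [(15, 15), (12, 3), (3, 12)]
        for y, x in inside + outside:
            bmap[y, x] = 1
        assert movement_index(bmap, region) == 7

    def test_conservation_over_partition(self, rng):
        bmap = (rng.random((40, 60)) < 0.2).astype(np.uint8)
        plate = build_grid(Rect(0, 0, 60, 40), rows=2, cols=3)
        total = sum(movement_index(bmap, m) for m in plate.regions.values())
        assert total == int(bmap.sum())

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValueError):
            movement_index(np.zeros((8, 8)), np.ones((10, 10), dtype=bool))

    def test_monotone_in_added_pixels(self):
        region = np.ones((6, 6), dtype=bool)
        bmap = np.zeros((6, 6), dtype=np.uint8)
        last = movement_index(bmap, region)
        for y in range(6):
            bmap[y, y] = 1
            now = movement_index(bmap, region)
            assert now >= last
            last = now


class TestNormalizeAggregate:
    @pytest.mark.parametrize("post, base, expected", [(50, 100, 0.5), (100, 100, 1.0)])
    def test_ratio(self, post, base, expected):
        assert normalize_index(post, base) == expected

    def test_zero_baseline_flags_undefined(self):
        assert math.isnan(normalize_index(10, 0))

    @pytest.mark.parametrize(
        "values, expected",
        [([0.2, 0.5, 0.9], 0.5), ([0.7], 0.7), ([0.2, 0.4, 0.6, 0.8], 0.5)],
    )
    def test_median_aggregation(self, values, expected):
        assert aggregate_replicates(values) == pytest.approx(expected)

    def test_nan_values_dropped_before_median(self):
        assert aggregate_replicates([math.nan, 0.3, 0.5, math.nan]) == pytest.approx(0.4)

    def test_all_undefined_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([math.nan, math.nan])


class TestScaleInvariance:
    @given(a=st.floats(0.1, 50.0), b=st.floats(0.0, 100.0))
    @settings(max_examples=15, deadline=None)
    def test_affine_intensity_invariance(self, a, b):
        """P -> a*P + b leaves the binary motion map unchanged (a > 0)."""
        rng = np.random.default_rng(99)
        frames = rng.integers(0, 200, size=(3, 20, 20)).astype(float)
        base = threshold_motion(temporal_variance(FrameStack(frames)))
        scaled = threshold_motion(temporal_variance(FrameStack(a * frames + b)))
        np.testing.assert_array_equal(base.values, scaled.values)

    def test_sample_vs_population_divisor_cancels(self, rng):
        """A uniform T/(T-1) factor on every variance leaves the map unchanged."""
        frames = rng.integers(0, 200, size=(3, 20, 20)).astype(float)
        vmap = temporal_variance(FrameStack(frames))
        sample = vmap.values * (3.0 / 2.0)
        np.testing.assert_array_equal(
            threshold_motion(vmap).values, threshold_motion(sample).values
        )


class TestMeasurePlate:
    def _series_from_stack(self, frames):
        base = FrameStack(frames, acquired_at_s=-5.0)
        post = FrameStack(frames.copy(), acquired_at_s=240.0)
        return AcquisitionSeries(baseline=[base], post=[post])

    @staticmethod
    def _flicker_frames():
        """Static background with one strongly flickering pixel per well."""
        frames = np.full((30, 40, 60), 20, dtype=np.uint8)
        plate = build_grid(Rect(0, 0, 60, 40), rows=2, cols=3)
        for rect in plate.rects.values():
            cy = (rect.top + rect.bottom) // 2
            cx = (rect.left + rect.right) // 2
            # bright only in the middle sampled frame -> trace (20, 255, 20)
            frames[10, cy, cx] = 255
        return frames, plate

    def test_post_equal_baseline_normalizes_to_one(self):
        frames, plate = self._flicker_frames()
        records = measure_plate(self._series_from_stack(frames), plate)
        assert len(records) == 6
        for r in records:
            assert r.raw_index == 1  # exactly the planted flicker pixel
            assert r.normalized_index == pytest.approx(1.0)

    def test_static_noise_free_plate_is_flagged(self):
        frames = np.full((30, 40, 60), 20, dtype=np.uint8)
        plate = build_grid(Rect(0, 0, 60, 40), rows=2, cols=3)
        records = measure_plate(self._series_from_stack(frames), plate)
        for r in records:
            assert r.raw_index == 0
            assert not r.is_defined

    def test_mismatched_dimensions_rejected(self, rng):
        frames = rng.integers(0, 256, size=(30, 20, 20)).astype(np.uint8)
        plate = build_grid(Rect(0, 0, 60, 40), rows=2, cols=3)
        with pytest.raises(ValueError):
            measure_plate(self._series_from_stack(frames), plate)

    def test_multiple_sequences_per_timepoint_medianed(self, rng):
        plate = build_grid(Rect(0, 0, 20, 20), rows=1, cols=1)
        base = FrameStack(
            rng.integers(0, 256, size=(30, 20, 20)).astype(np.uint8),
            acquired_at_s=-5.0,
        )
        posts = [
            FrameStack(
                rng.integers(0, 256, size=(30, 20, 20)).astype(np.uint8),
                acquired_at_s=240.0,
            )
            for _ in range(3)
        ]
        records = measure_plate(AcquisitionSeries([base], posts), plate)
        assert len(records) == 1  # three sequences, one timepoint, one record

    def test_treated_wells_slow_down_vehicle_wells_do_not(self):
        """Halved motility after dosing lowers the treated wells' normalized
        index while vehicle wells stay near 1 (median over 20 seeds)."""
        treated_meds, vehicle_meds = [], []
        for seed in range(20):
            cfg = SimulationConfig.reduced(rows=2, cols=3, seed=seed)
            # concentration at the fitted midpoint => motility factor 0.5
            dose_map = {"A1": 1e-7, "B1": 1e-7}
            series, _ = simulate_series(cfg, dose_map, true_I=-7.0, true_H=1.0)
            records = measure_plate(series, cfg.plate_map())
            for r in records:
                if not r.is_defined:
                    continue
                (treated_meds if r.well in dose_map else vehicle_meds).append(
                    r.normalized_index
                )
        assert np.median(treated_meds) < 0.8
        assert 0.8 < np.median(vehicle_meds) < 1.2

    def test_per_well_threshold_scope_runs(self):
        frames, plate = self._flicker_frames()
        params = ParagonParams(threshold_scope="per-well")
        records = measure_plate(self._series_from_stack(frames), plate, params)
        assert all(r.raw_index == 1 for r in records)
        assert all(r.normalized_index == pytest.approx(1.0) for r in records)
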