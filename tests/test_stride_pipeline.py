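import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitdtw import (
    ChannelError,
    ConfigError,
    DegenerateSignalError,
    GridError,
    NoStridesError,
    PipelineConfig,
    lowpass_filter,
)
from gaitdtw.event_detection import detect_events
from gaitdtw.stride_pipeline import (
    NormalizedStride,
    StrideSegment,
    build_fused_stride,
    extract_strides,
    fuse,
    mean_stride,
    resample_stride,
    standardize,
)
from gaitdtw.synthetic import AsymmetryPreset, GaitParams, synth_foot, synth_walk


def seg_from(samples, closing=0.0, duration=1.0, swing=0.4, channel="gyro"):
    return StrideSegment(
        channel=channel,
        samples=np.asarray(samples, float),
        closing_value=closing,
        duration=duration,
        swing_duration=swing,
        max_angular_velocity=float(np.max(samples)) if channel == "gyro" else None,
    )


def norm(values):
    values = np.asarray(values, float)
    return NormalizedStride(grid=np.linspace(0, 100, values.size), values=values)


class TestExtractStrides:
    def test_n_minus_one_segments_from_n_heel_strikes(self, detected):
        rec, ev, truth = detected
        segs = extract_strides(rec, ev, "gyro")
        assert len(segs) == len(ev.hs) - 1

    def test_durations_match_planted_stride_times(self, detected):
        rec, ev, truth = detected
        segs = extract_strides(rec, ev, "gyro")
        mean_dur = np.mean([s.duration for s in segs])
        assert mean_dur == pytest.approx(np.mean(truth.stride_duration), abs=0.02)

    def test_swing_durations_match_planted(self, detected):
        rec, ev, truth = detected
        segs = extract_strides(rec, ev, "gyro")
        mean_swing = np.mean([s.swing_duration for s in segs])
        assert mean_swing == pytest.approx(np.mean(truth.swing_duration), abs=0.03)

    def test_max_angular_velocity_only_on_gyro(self, detected):
        rec, ev, truth = detected
        gyro_segs = extract_strides(rec, ev, "gyro")
        pres_segs = extract_strides(rec, ev, "pressure")
        assert all(s.max_angular_velocity is not None for s in gyro_segs)
        assert all(s.max_angular_velocity is None for s in pres_segs)

    def test_unknown_channel_rejected(self, detected):
        rec, ev, _ = detected
        with pytest.raises(ChannelError):
            extract_strides(rec, ev, "magnetometer")


class TestResampleStride:
    def test_linear_ramp_stays_linear(self):
        ramp = np.linspace(0, 10, 8)
        out = resample_stride(seg_from(ramp[:-1], closing=float(ramp[-1])), 101)
        fit = np.polyfit(out.grid, out.values, 1)
        np.testing.assert_allclose(
            out.values, np.polyval(fit, out.grid), atol=1e-9
        )
        assert out.values[0] == pytest.approx(0.0, abs=1e-12)
        assert out.values[-1] == pytest.approx(10.0, abs=1e-12)

    def test_constant_segment_stays_constant(self):
        out = resample_stride(seg_from(np.full(9, 4.2), closing=4.2), 51)
        np.testing.assert_allclose(out.values, 4.2, atol=1e-12)

    def test_monotone_input_gives_strictly_monotone_output(self):
        rng = np.random.default_rng(3)
        y = np.cumsum(rng.uniform(0.1, 1.0, 12))
        out = resample_stride(seg_from(y[:-1], closing=float(y[-1])), 101)
        assert np.all(np.diff(out.values) > 0)  # brute-force monotonicity scan

    def test_no_overshoot_beyond_data_extrema(self, detected):
        rec, ev, _ = detected
        for seg in extract_strides(rec, ev, "gyro"):
            out = resample_stride(seg, 101)
            data = np.append(seg.samples, seg.closing_value)
            assert out.values.max() <= data.max() + 1e-9
            assert out.values.min() >= data.min() - 1e-9

    def test_endpoints_preserved(self, detected):
        rec, ev, _ = detected
        for seg in extract_strides(rec, ev, "pressure"):
            out = resample_stride(seg, 101)
            assert abs(out.values[0] - seg.samples[0]) < 1e-9
            assert abs(out.values[-1] - seg.closing_value) < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ConfigError):
            resample_stride(seg_from([0.0, 1.0, 2.0]), 2)


class TestMeanStride:
    def test_mean_of_one_is_itself(self):
        s = norm([1.0, 2.0, 3.0])
        out = mean_stride([s])
        np.testing.assert_array_equal(out.values, s.values)

    def test_opposite_strides_cancel(self):
        v = np.array([1.0, -2.0, 3.0])
        out = mean_stride([norm(v), norm(-v)])
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_noisy_copies_converge_to_template(self):
        rng = np.random.default_rng(9)
        template = np.sin(np.linspace(0, 2 * np.pi, 101))
        sigma, n = 0.3, 10
        for _ in range(20):  # Monte-Carlo repeats
            strides = [norm(template + rng.normal(0, sigma, 101)) for _ in range(n)]
            out = mean_stride(strides)
            assert np.max(np.abs(out.values - template)) < 4 * sigma / np.sqrt(n)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        strides = [norm(rng.normal(size=11)) for _ in range(5)]
        a = mean_stride(strides)
        b = mean_stride(strides[::-1])
        np.testing.assert_allclose(a.values, b.values, atol=1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(NoStridesError):
            mean_stride([])

    def test_mismatched_grids_rejected(self):
        with pytest.raises(GridError):
            mean_stride([norm([0.0, 1.0]), norm([0.0, 1.0, 2.0])])


class TestStandardize:
    def test_two_point_example(self):
        out = standardize(norm([0.0, 2.0]))
        np.testing.assert_allclose(out.values, [-1.0, 1.0], atol=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateSignalError):
            standardize(norm(np.full(10, 3.0)))

    def test_output_has_zero_mean_unit_population_sd(self, detected):
        rec, ev, _ = detected
        seg = extract_strides(rec, ev, "gyro")[0]
        out = standardize(resample_stride(seg, 101))
        assert abs(np.mean(out.values)) < 1e-9
        assert abs(np.std(out.values) - 1.0) < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        once = standardize(norm(rng.normal(2.0, 3.0, 64)))
        twice = standardize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-50, max_value=50),
    )
    def test_affine_invariance_for_positive_scale(self, a, b):
        x = np.sin(np.linspace(0, 3, 32))
        base = standardize(norm(x))
        scaled = standardize(norm(a * x + b))
        np.testing.assert_allclose(scaled.values, base.values, atol=1e-9)


class TestFuse:
    def test_superposition_of_opposites_cancels(self):
        v = np.sin(np.linspace(0, 2 * np.pi, 101))
        out = fuse(norm(v), norm(-v), side="left")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_fused_mean_is_zero_for_standardized_inputs(self, detected, cfg):
        rec, ev, _ = detected
        parts = []
        for channel in ("gyro", "pressure"):
            segs = extract_strides(rec, ev, channel)
            parts.append(
                standardize(mean_stride([resample_stride(s, 101) for s in segs]))
            )
        out = fuse(parts[0], parts[1], side="left", n_strides=len(segs))
        assert abs(np.mean(out.values)) < 1e-9

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridError):
            fuse(norm(np.zeros(11)), norm(np.zeros(21)), side="left")


class TestBuildFusedStride:
    def test_deterministic_on_identical_input(self, normal_foot, cfg):
        rec, _ = normal_foot
        a = build_fused_stride(rec, cfg)
        b = build_fused_stride(rec, cfg)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.n_strides == b.n_strides

    def test_symmetric_walk_feet_nearly_coincide(self, cfg):
        walk = synth_walk(GaitParams(seed=21), AsymmetryPreset(severity=0.0))
        left = build_fused_stride(walk.left, cfg)
        right = build_fused_stride(walk.right, cfg)
        assert np.max(np.abs(left.values - right.values)) < 0.5

    def test_asymmetric_walk_feet_differ_more_than_symmetric(self, cfg):
        sym = synth_walk(GaitParams(seed=22), AsymmetryPreset(severity=0.0))
        asym = synth_walk(GaitParams(seed=22), AsymmetryPreset(severity=1.0))

        def gap(walk):
            l = build_fused_stride(walk.left, cfg)
            r = build_fused_stride(walk.right, cfg)
            return np.max(np.abs(l.values - r.values))

        assert gap(asym) > 2 * gap(sym)

    def test_filter_then_detect_errors_propagate(self, cfg):
        from .test_signal_io import make_rec

        with pytest.raises(NoStridesError):
            build_fused_stride(make_rec(np.zeros(400)), cfg)
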