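"""Windowing, SMA/gravity features, decision tree, end-to-end labels."""

import numpy as np
import pytest

from triact.classify import (
    AlgorithmParameters,
    WindowFeatures,
    class_totals,
    classify_recording,
    classify_window,
    compute_mean_gravity,
    compute_sma_cps,
    segment_windows,
)
from triact.filters import (
    extract_body_acceleration,
    extract_gravitational_acceleration,
    moving_average_filter,
)
from triact.io import AccelerometerRecording, ActivityLabel
from triact.simulate import ActivitySegmentSpec, generate_segment

RATE = 25.0
D, S, Z = ActivityLabel.DYNAMIC, ActivityLabel.STANDING, ActivityLabel.SEDENTARY


def features(sma, gx):
    return WindowFeatures(index=0, sma_cps=sma, ga_mean=(gx, 0.0, 0.0), n_samples=50)


class TestSegmentation:
    @pytest.mark.parametrize(
        "length,ws,expected_windows,expected_tail",
        [
            (7500, 2.0, 150, 0),
            (7525, 2.0, 150, 25),
            (10, 2.0, 0, 10),
        ],
    )
    def test_window_arithmetic(self, length, ws, expected_windows, expected_tail):
        windows = segment_windows(length, RATE, ws)
        assert len(windows) == expected_windows
        n = int(round(ws * RATE))
        assert all(b - a == n for a, b in windows)
        covered = expected_windows * n
        assert length - covered == expected_tail

    def test_windows_are_consecutive_and_non_overlapping(self):
        windows = segment_windows(500, RATE, 1.0)
        for (a1, b1), (a2, _) in zip(windows, windows[1:]):
            assert b1 == a2

    def test_empty_window_size_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(100, RATE, 0.001)


class TestWindowFeatures:
    def test_sma_zero_input(self):
        assert compute_sma_cps(np.zeros((50, 3)), 2.0) == 0.0

    def test_sma_hand_sum(self):
        w = np.zeros((50, 3))
        w[:, 0] = 0.1
        assert compute_sma_cps(w, 2.0) == pytest.approx(2.5)

    def test_sma_matches_double_loop(self, rng):
        w = rng.normal(0, 0.3, (50, 3))
        total = 0.0
        for i in range(50):
            for axis in range(3):
                total += abs(w[i, axis])
        assert compute_sma_cps(w, 2.0) == pytest.approx(total / 2.0, abs=1e-12)

    def test_sma_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_sma_cps(np.empty((0, 3)), 2.0)

    def test_mean_gravity_constant(self):
        w = np.tile([0.8, 0.0, 0.6], (50, 1))
        assert compute_mean_gravity(w) == pytest.approx((0.8, 0.0, 0.6))

    def test_mean_gravity_alternating_cancels(self):
        w = np.zeros((50, 3))
        w[::2, 0] = 1.0
        w[1::2, 0] = -1.0
        assert compute_mean_gravity(w)[0] == pytest.approx(0.0, abs=1e-12)

    def test_mean_gravity_matches_loop(self, rng):
        w = rng.normal(0, 0.5, (37, 3))
        expected = [sum(w[i, a] for i in range(37)) / 37 for a in range(3)]
        np.testing.assert_allclose(compute_mean_gravity(w), expected, atol=1e-12)


class TestDecisionTree:
    PARAMS = AlgorithmParameters(window_size=2.0, pa_threshold=7.0, so_threshold=0.8)

    # nine boundary/interior combinations around PA Th = 7 and SO Th = 0.8
    TRUTH_TABLE = [
        (10.0, 0.95, D),  # clearly active
        (10.0, 0.17, D),  # activity dominates posture
        (7.0, 0.5, D),    # SMA exactly at threshold -> dynamic (>= rule)
        (3.0, 0.95, S),   # quiet, upright
        (3.0, 0.8, S),    # gravity exactly at threshold -> standing (>= rule)
        (3.0, 0.17, Z),   # quiet, thigh ~80 deg from vertical
        (6.99, 0.79, Z),  # just inside both boundaries
        (0.0, 0.0, Z),    # lying, no movement
        (3.0, -0.95, Z),  # inverted axis without sign flip is not standing
    ]

    @pytest.mark.parametrize("sma,gx,expected", TRUTH_TABLE)
    def test_truth_table(self, sma, gx, expected):
        assert classify_window(features(sma, gx), self.PARAMS) is expected

    def test_orientation_sign_flip_recovers_standing(self):
        params = self.PARAMS.replace(orientation_sign=-1)
        assert classify_window(features(3.0, -0.95), params) is S


class TestClassifyRecording:
    def test_static_upright_is_standing(self):
        rec = AccelerometerRecording(np.tile([1.0, 0, 0], (int(60 * RATE), 1)), RATE)
        series = classify_recording(rec)
        assert set(series.labels) == {S}

    def test_static_reclined_is_sedentary(self):
        rec = AccelerometerRecording(
            np.tile([0.17, 0, 0.98], (int(60 * RATE), 1)), RATE
        )
        series = classify_recording(rec)
        assert set(series.labels) == {Z}

    def test_walking_segment_mostly_dynamic(self, rng):
        spec = ActivitySegmentSpec(D, 60, thigh_angle=10, ba_intensity=15.0)
        samples, _ = generate_segment(spec, RATE, rng)
        series = classify_recording(AccelerometerRecording(samples, RATE))
        frac = np.mean([l is D for l in series.labels])
        assert frac >= 0.95

    def test_matches_literal_reference_implementation(self, rng):
        """Vectorized pipeline labels equal a straight-line loop version."""
        samples = np.clip(rng.normal(0, 0.5, (int(10 * RATE), 3)), -8, 8)
        rec = AccelerometerRecording(samples, RATE)
        params = AlgorithmParameters()
        series = classify_recording(rec, params)

        smoothed = moving_average_filter(rec, params.filter_constants.ma_window)
        ba = extract_body_acceleration(smoothed, params.filter_constants).samples
        ga = extract_gravitational_acceleration(
            smoothed, params.filter_constants
        ).samples
        n = int(round(params.window_size * RATE))
        ref_labels = []
        for j in range(samples.shape[0] // n):
            sma = 0.0
            gx = 0.0
            for i in range(j * n, (j + 1) * n):
                for axis in range(3):
                    sma += abs(ba[i, axis])
                gx += ga[i, 0]
            sma /= n / RATE
            gx /= n
            if sma >= params.pa_threshold:
                ref_labels.append(D)
            elif gx >= params.so_threshold:
                ref_labels.append(S)
            else:
                ref_labels.append(Z)
        assert series.labels == ref_labels

    def test_dc_offset_does_not_change_dynamic_split(self, rng):
        spec = ActivitySegmentSpec(D, 30, thigh_angle=10, ba_intensity=10.0)
        samples, _ = generate_segment(spec, RATE, rng)
        rec = AccelerometerRecording(samples, RATE)
        shifted = AccelerometerRecording(samples + np.array([0.3, -0.2, 0.1]), RATE)
        s1 = classify_recording(rec)
        s2 = classify_recording(shifted)
        for f1, f2 in zip(s1.features, s2.features):
            assert f2.sma_cps == pytest.approx(f1.sma_cps, abs=1e-6)

    def test_threshold_monotonicity(self, rng):
        samples = np.clip(rng.normal(0.2, 0.4, (int(30 * RATE), 3)), -8, 8)
        rec = AccelerometerRecording(samples, RATE)
        dynamic_time = []
        for pa in [3, 5, 7, 9, 12]:
            totals = class_totals(
                classify_recording(rec, AlgorithmParameters(pa_threshold=pa))
            )
            dynamic_time.append(totals[D])
        assert dynamic_time == sorted(dynamic_time, reverse=True)

        standing_time = []
        static = AccelerometerRecording(
            np.tile([0.85, 0, 0.5], (int(30 * RATE), 1)), RATE
        )
        for so in [0.5, 0.8, 0.9]:
            totals = class_totals(
                classify_recording(static, AlgorithmParameters(so_threshold=so))
            )
            standing_time.append(totals[S])
        assert standing_time == sorted(standing_time, reverse=True)

    def test_time_conservation_random_durations(self, rng):
        for _ in range(20):
            duration = float(rng.uniform(5, 40))
            ws = float(rng.uniform(0.5, 10))
            n = int(round(duration * RATE))
            rec = AccelerometerRecording(
                np.clip(rng.normal(0, 0.3, (n, 3)), -8, 8), RATE
            )
            series = classify_recording(rec, AlgorithmParameters(window_size=ws))
            covered = sum(class_totals(series).values())
            assert covered + series.dropped_tail == pytest.approx(
                rec.duration_s, abs=1.0 / RATE
            )


class TestClassTotals:
    def test_counting(self):
        labels = [D] * 100 + [S] * 30 + [Z] * 20
        feats = [features(0, 0) for _ in labels]
        from triact.classify import ClassifiedSeries

        series = ClassifiedSeries(
            labels=labels,
            window_size=2.0,
            features=[
                WindowFeatures(index=i, sma_cps=0, ga_mean=(0, 0, 0), n_samples=50)
                for i in range(len(labels))
            ],
        )
        assert class_totals(series) == {D: 200.0, S: 60.0, Z: 40.0}

    def test_empty_series(self):
        from triact.classify import ClassifiedSeries

        series = ClassifiedSeries(labels=[], window_size=2.0, features=[])
        assert class_totals(series) == {D: 0.0, S: 0.0, Z: 0.0}

    def test_matches_loop_count(self, rng):
        from triact.classify import ClassifiedSeries

        labels = [list(ActivityLabel)[i] for i in rng.integers(0, 3, 200)]
        series = ClassifiedSeries(
            labels=labels,
            window_size=1.5,
            features=[
                WindowFeatures(index=i, sma_cps=0, ga_mean=(0, 0, 0), n_samples=38)
                for i in range(len(labels))
            ],
        )
        totals = class_totals(series)
        for label in ActivityLabel:
            assert totals[label] == pytest.approx(
                1.5 * sum(1 for l in labels if l is label)
            )


def test_window_output_table_layout(rng):
    rec = AccelerometerRecording(np.tile([1.0, 0, 0], (int(10 * RATE), 1)), RATE)
    df = classify_recording(rec).to_frame()
    assert list(df.columns) == [
        "window_index", "start_s", "end_s", "sma_cps", "ga_x", "ga_y", "ga_z", "label",
    ]
    assert len(df) == 5
    assert (df["end_s"] - df["start_s"]).eq(2.0).all()
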