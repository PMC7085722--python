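"""Kalman smoothing, baselining, unit conversion, per-second alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eskin_lpm as el
from eskin_lpm.preprocessing import KalmanParams


def _series(values, rate_hz=15.0, unit="ADU", channel="test"):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / rate_hz * 1000.0
    return el.TimeSeries(t, values, unit=unit, channel=channel)


def _kalman_reference(values, r=4.0, p=4.0, q=0.05):
    """Independent step-by-step scalar recurrence."""
    out = [values[0]]
    last = values[0]
    for meas in values[1:]:
        k = p / (p + r)
        cur = last + k * (meas - last)
        p = (1 - k) * p + abs(last - cur) * q
        out.append(cur)
        last = cur
    return np.asarray(out)


class TestKalmanSmooth:
    def test_constant_input_is_fixed_point(self):
        out = el.kalman_smooth(_series([7.0] * 30))
        assert np.all(out.values == 7.0)

    def test_first_update_is_midpoint(self):
        # p = r = 4 -> k = 0.5 on the first update
        out = el.kalman_smooth(_series([10.0, 20.0]))
        assert out.values[1] == pytest.approx(15.0)

    def test_matches_reference_recurrence(self):
        rng = np.random.default_rng(1)
        values = rng.normal(1000, 50, size=50)
        out = el.kalman_smooth(_series(values))
        assert np.allclose(out.values, _kalman_reference(values), atol=1e-12, rtol=0)

    def test_empty_series_rejected(self):
        with pytest.raises(el.InsufficientDataError):
            el.kalman_smooth(_series([]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=2, max_size=60))
    def test_estimate_is_convex_combination(self, values):
        out = el.kalman_smooth(_series(values)).values
        for i in range(1, len(values)):
            lo = min(out[i - 1], values[i]) - 1e-9
            hi = max(out[i - 1], values[i]) + 1e-9
            assert lo <= out[i] <= hi

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 10, size=2000)
        out = el.kalman_smooth(_series(values)).values
        assert np.var(out) < np.var(values)


class TestBaseline:
    def test_constant_stream(self):
        assert el.compute_baseline(_series([1000.0] * 150)) == 1000.0

    def test_enumerated_window_mean(self):
        # 5 s at 15 Hz of values 1..75 -> mean 38
        assert el.compute_baseline(_series(np.arange(1, 76))) == pytest.approx(38.0)

    def test_short_series_rejected(self):
        with pytest.raises(el.InsufficientDataError):
            el.compute_baseline(_series(np.ones(45)))  # 3 s at 15 Hz


class TestAduToResistance:
    @pytest.mark.parametrize("adu,ohms", [(4096, 660.0), (0, 0.0), (1024, 165.0)])
    def test_closed_form(self, adu, ohms):
        assert el.adu_to_resistance(float(adu)) == pytest.approx(ohms)

    def test_linearity(self):
        x = np.array([100.0, 500.0, 1000.0])
        assert np.allclose(el.adu_to_resistance(2.0 * x), 2.0 * el.adu_to_resistance(x))

    def test_out_of_range_rejected(self):
        with pytest.raises(el.RangeError):
            el.adu_to_resistance(5000.0)


class TestResistanceChange:
    def test_rest_is_zero(self):
        s = _series([660.0] * 10, unit="ohm")
        assert np.all(el.resistance_change(s, 660.0).values == 0.0)

    def test_threshold_scale_subtraction(self):
        s = _series([653.1], unit="ohm")
        assert el.resistance_change(s, 660.0).values[0] == pytest.approx(6.9)

    def test_nonnegative_during_noiseless_flexion(self):
        from conftest import noiseless_session

        sess = noiseless_session(el.Movement.FLEXION, reps_per_set=2, n_sets=1)
        stream = sess.eskin_streams[el.Placement.BOTTOM_VERTICAL]
        ohm = el.adu_to_resistance(stream)
        change = el.resistance_change(ohm, el.compute_baseline(ohm))
        assert np.all(change.values >= -1e-9)


class TestDownsample:
    def test_bin_mean(self):
        # 19 samples inside second 7
        t = 7000.0 + np.linspace(0, 999, 19)
        s = el.TimeSeries(t, np.arange(19.0), unit="degree", channel="angle")
        out = el.downsample_per_second(s)
        assert len(out) == 1
        assert out.timestamps_ms[0] == 7000.0
        assert out.values[0] == pytest.approx(np.mean(np.arange(19.0)))

    def test_singleton_bins_unchanged(self):
        s = el.TimeSeries(np.arange(10) * 1000.0, np.arange(10.0), "degree", "a")
        out = el.downsample_per_second(s)
        assert np.array_equal(out.values, s.values)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(0, 20000, size=300))
        v = rng.normal(size=300)
        s = el.TimeSeries(t, v, unit="ohm", channel="x")
        out = el.downsample_per_second(s)
        # naive double loop
        expected = {}
        for ti, vi in zip(t, v):
            expected.setdefault(int(ti // 1000), []).append(vi)
        for sec, val in zip(out.timestamps_ms / 1000.0, out.values):
            assert val == pytest.approx(np.mean(expected[int(sec)]))
        assert len(out) == len(expected)


class TestAlign:
    def test_identical_labels_all_retained(self):
        a = el.TimeSeries(np.arange(10) * 1000.0, np.ones(10), "ohm", "e")
        b = el.TimeSeries(np.arange(10) * 1000.0, np.zeros(10), "degree", "angle")
        aligned = el.align_streams({"e": a}, b)
        assert len(aligned) == 10
        assert aligned.dropped_bins == 0

    def test_disjoint_labels_rejected(self):
        a = el.TimeSeries(np.arange(5) * 1000.0, np.ones(5), "ohm", "e")
        b = el.TimeSeries((np.arange(5) + 10) * 1000.0, np.zeros(5), "degree", "angle")
        with pytest.raises(el.AlignmentError):
            el.align_streams({"e": a}, b)

    def test_three_second_offset_keeps_seven_bins(self):
        a = el.TimeSeries(np.arange(10) * 1000.0, np.ones(10), "ohm", "e")
        b = el.TimeSeries((np.arange(10) + 3) * 1000.0, np.zeros(10), "degree", "angle")
        aligned = el.align_streams({"e": a}, b)
        assert len(aligned) == 7
        assert np.all(np.diff(aligned.seconds) > 0)
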