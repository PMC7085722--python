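"""Onset detection, response-time difference, rule-based classification."""

import numpy as np
import pytest

import eskin_lpm as el
from eskin_lpm.core import Movement, Placement, STATIC
from eskin_lpm.detection import (
    OnsetEvent,
    classify_movement,
    detect_onsets,
    response_time_difference,
)
from eskin_lpm.pipeline import detect_session
from conftest import noiseless_session


def _series(values, rate_hz=1.0, channel="x", unit="ohm"):
    values = np.asarray(values, dtype=float)
    t = np.arange(len(values)) / rate_hz * 1000.0
    return el.TimeSeries(t, values, unit=unit, channel=channel)


def _scan_oracle(t_s, values, rest, threshold, refractory_s):
    """Independent exhaustive first-crossing scan."""
    events = []
    armed = True
    last = -np.inf
    for ti, vi in zip(t_s, values):
        if abs(vi - rest) > threshold:
            if armed and ti - last >= refractory_s:
                events.append(ti)
                last = ti
            armed = False
        else:
            armed = True
    return events


class TestDetectOnsets:
    def test_never_exceeding_band_gives_no_events(self):
        assert detect_onsets(_series(np.full(50, 2.0)), 0.0, 3.0) == []

    def test_step_crossing(self):
        values = np.where(np.arange(30) >= 10, 10.0, 0.0)
        events = detect_onsets(_series(values), 0.0, 3.0)
        assert len(events) == 1
        assert events[0].onset_time_s == 10.0
        assert events[0].direction == 1

    def test_refractory_suppresses_nearby_crossings(self):
        values = np.zeros(30)
        values[5] = 10.0  # spike, back inside band, spike again 1 s later
        values[6] = 0.0
        values[7] = 10.0
        events = detect_onsets(_series(values), 0.0, 3.0, refractory_s=3.0)
        assert [e.onset_time_s for e in events] == [5.0]

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            values = rng.normal(0, 4, size=rng.integers(20, 400))
            s = _series(values)
            got = [e.onset_time_s for e in detect_onsets(s, 0.0, 5.0, 3.0)]
            want = _scan_oracle(s.timestamps_ms / 1000.0, values, 0.0, 5.0, 3.0)
            assert got == want

    def test_counts_repetitions_in_synthetic_session(self, flexion_session, flexion_aligned):
        for name, values in flexion_aligned.eskin_values.items():
            if name in (Placement.TOP_VERTICAL.value, Placement.BOTTOM_VERTICAL.value):
                s = _series(values, channel=name)
                events = detect_onsets(s, 0.0, 6.9)
                assert len(events) == 15


class TestResponseTimeDifference:
    def test_identical_onsets_give_zero(self):
        evs = [OnsetEvent("a", float(t), 1) for t in (5, 20, 35)]
        assert response_time_difference(evs, evs) == 0.0

    def test_constant_lead(self):
        e = [OnsetEvent("e", float(t), 1) for t in (4, 19, 34)]
        a = [OnsetEvent("a", float(t), 1) for t in (5, 20, 35)]
        assert response_time_difference(e, a) == pytest.approx(1.0)

    def test_unequal_counts_rejected(self):
        e = [OnsetEvent("e", 4.0, 1)]
        a = [OnsetEvent("a", 5.0, 1), OnsetEvent("a", 20.0, 1)]
        with pytest.raises(el.PairingError):
            response_time_difference(e, a)

    def test_recovers_configured_lead_under_noise(self):
        """~1 s skin lead recovered within one analysis bin across seeds,
        up to noise of 10% of the peak response (~13 ohm ~ 81 ADU)."""
        from eskin_lpm.synthetic import SessionScript, default_profiles

        script = SessionScript(profiles=[default_profiles()[Movement.FLEXION]])
        for noise_adu in (2.0, 81.0):
            for seed in range(10):
                sess = el.generate_session(script, noise_sd_adu=noise_adu, seed=seed)
                aligned = el.preprocess_session(sess.eskin_streams, sess.angle_stream)
                det = detect_session(aligned, sess.truth)
                diff = det["response_time_s"]["flexion"]
                assert diff is not None
                assert abs(diff - 1.0) <= 1.0


class TestClassifyMovement:
    def test_all_flat_is_static(self):
        channels = {p: np.zeros(20) for p in Placement}
        label = classify_movement(channels)
        assert label.label == STATIC
        assert label.confidence == "high"

    @pytest.mark.parametrize("movement", list(Movement))
    def test_noiseless_sessions_classified_correctly(self, movement):
        sess = noiseless_session(movement, reps_per_set=2, n_sets=1, seed=11,
                                 onset_lead_s=1.0, quantize=True)
        aligned = el.preprocess_session(sess.eskin_streams, sess.angle_stream)
        det = detect_session(aligned, sess.truth)
        for row in det["labels"]:
            assert row["label"] == movement.value

    def test_lateral_flexion_side_from_contralateral_magnitude(self):
        n = 20
        bump = np.concatenate([np.zeros(5), 40 * np.sin(np.linspace(0, np.pi, 10)), np.zeros(5)])
        channels = {
            Placement.LEFT_DIAGONAL: 0.5 * bump,
            Placement.RIGHT_DIAGONAL: bump,
            Placement.TOP_VERTICAL: np.zeros(n),
            Placement.BOTTOM_VERTICAL: np.zeros(n),
        }
        assert classify_movement(channels).label == "left_lateral_flexion"

    def test_rotation_side_from_leading_channel(self):
        bump = np.concatenate([np.zeros(5), 40 * np.sin(np.linspace(0, np.pi, 10)), np.zeros(5)])
        delayed = np.roll(bump, 3)
        channels = {
            Placement.LEFT_DIAGONAL: delayed,
            Placement.RIGHT_DIAGONAL: bump,
            Placement.TOP_VERTICAL: np.zeros(20),
            Placement.BOTTOM_VERTICAL: np.zeros(20),
        }
        assert classify_movement(channels).label == "left_rotation"
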