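"""Synthetic session generator: trajectories, coupling, ground truth."""

import numpy as np
import pytest

import eskin_lpm as el
from eskin_lpm.core import Movement, Placement
from eskin_lpm.synthetic import (
    MovementProfile,
    SessionScript,
    default_coupling,
    default_profiles,
)
from conftest import noiseless_session


class TestAngleTrajectory:
    def test_flexion_reaches_and_holds_peak(self):
        prof = default_profiles()[Movement.FLEXION]
        prof = MovementProfile(Movement.FLEXION, 55.0, hold_duration=10.0, rest_jitter_s=0.0)
        ts = el.generate_angle_trajectory(prof, n_reps=3, rate_hz=20.0)
        assert ts.values.max() == pytest.approx(55.0, abs=1e-9)
        # held at peak for ~10 s per repetition
        per_rep_hold = np.sum(ts.values > 54.999) / 20.0 / 3
        assert per_rep_hold == pytest.approx(10.0, abs=0.2)

    def test_zero_peak_is_all_zero(self):
        prof = MovementProfile(Movement.FLEXION, 0.0)
        ts = el.generate_angle_trajectory(prof, n_reps=2, rate_hz=15.0)
        assert np.all(ts.values == 0.0)

    def test_extension_reaches_negative_peak(self):
        prof = MovementProfile(Movement.EXTENSION, -12.0, rest_jitter_s=0.0)
        ts = el.generate_angle_trajectory(prof, n_reps=2, rate_hz=20.0)
        assert ts.values.min() == pytest.approx(-12.0, abs=1e-9)

    def test_invalid_parameters_rejected(self):
        prof = MovementProfile(Movement.FLEXION, 55.0)
        with pytest.raises(el.ParameterError):
            el.generate_angle_trajectory(prof, n_reps=0, rate_hz=15.0)
        with pytest.raises(el.ParameterError):
            el.generate_angle_trajectory(prof, n_reps=1, rate_hz=0.0)

    def test_sign_convention_enforced(self):
        with pytest.raises(el.ParameterError):
            MovementProfile(Movement.EXTENSION, +12.0)
        with pytest.raises(el.ParameterError):
            MovementProfile(Movement.FLEXION, -55.0)


class TestAngleToStrain:
    def test_linear_coupling_peak(self):
        # 0.3/55 strain per degree at 55 deg -> 0.30 peak strain
        prof = MovementProfile(Movement.FLEXION, 55.0, rest_jitter_s=0.0)
        angle = el.generate_angle_trajectory(prof, n_reps=1, rate_hz=20.0)
        strain = el.angle_to_strain(
            angle, default_coupling(), Movement.FLEXION, Placement.BOTTOM_VERTICAL
        )
        assert strain.values.max() == pytest.approx(0.30, abs=1e-9)
        assert strain.unit == "strain"

    def test_zero_angle_gives_zero_strain(self):
        angle = el.TimeSeries(np.arange(10) * 100.0, np.zeros(10), "degree", "angle")
        strain = el.angle_to_strain(
            angle, default_coupling(), Movement.FLEXION, Placement.BOTTOM_VERTICAL
        )
        assert np.all(strain.values == 0.0)

    def test_decoupled_channel_is_silent(self):
        prof = MovementProfile(Movement.LEFT_ROTATION, 30.0, rest_jitter_s=0.0)
        angle = el.generate_angle_trajectory(prof, n_reps=1, rate_hz=20.0)
        strain = el.angle_to_strain(
            angle, default_coupling(), Movement.LEFT_ROTATION, Placement.BOTTOM_VERTICAL
        )
        assert np.all(strain.values == 0.0)

    def test_missing_coupling_entry_rejected(self):
        coupling = el.CouplingModel(coupling={})
        angle = el.TimeSeries(np.arange(5) * 100.0, np.zeros(5), "degree", "angle")
        with pytest.raises(el.ConfigurationError):
            el.angle_to_strain(angle, coupling, Movement.FLEXION, Placement.TOP_VERTICAL)


class TestGenerateSession:
    def test_default_script_has_15_reps_per_movement(self, flexion_session):
        assert len(flexion_session.truth) == 15

    def test_same_seed_is_byte_identical(self, flexion_script):
        a = el.generate_session(flexion_script, seed=5)
        b = el.generate_session(flexion_script, seed=5)
        assert a.equals(b)

    def test_different_seed_differs(self, flexion_script):
        a = el.generate_session(flexion_script, seed=5)
        b = el.generate_session(flexion_script, seed=6)
        assert not a.equals(b)

    def test_truth_lead_ordering(self, flexion_session):
        for rep in flexion_session.truth:
            assert rep.skin_onset_ms <= rep.angle_onset_ms
            assert rep.angle_onset_ms - rep.skin_onset_ms == pytest.approx(1000.0)

    def test_truth_onsets_inside_stream_span(self, flexion_session):
        t0 = flexion_session.angle_stream.timestamps_ms[0]
        t1 = flexion_session.angle_stream.timestamps_ms[-1]
        for rep in flexion_session.truth:
            assert t0 <= rep.skin_onset_ms <= t1
            assert t0 <= rep.angle_onset_ms <= t1

    def test_sample_count_conservation(self, flexion_session):
        duration_s = flexion_session.truth[-1].end_ms / 1000.0
        for placement, stream in flexion_session.eskin_streams.items():
            expected = stream.duration_s * 15.0
            assert abs(len(stream) - 1 - expected) <= 1
        n_angle = len(flexion_session.angle_stream)
        expected = flexion_session.angle_stream.duration_s * flexion_session.angle_rate_hz
        assert abs(n_angle - 1 - expected) <= 1

    def test_angle_rate_drawn_in_band(self, flexion_script):
        rates = [
            el.generate_session(flexion_script, seed=s).angle_rate_hz for s in range(5)
        ]
        assert all(19.0 <= r <= 19.8 for r in rates)

    def test_invalid_rate_rejected(self, flexion_script):
        with pytest.raises(el.GenerationError):
            el.generate_session(flexion_script, eskin_rate_hz=0.0, seed=1)


class TestCouplingDominance:
    """The generator must encode the placement findings the classifier uses."""

    @staticmethod
    def _peak_change(session, placement):
        stream = session.eskin_streams[placement]
        ohm = el.adu_to_resistance(stream)
        baseline = el.compute_baseline(ohm)
        return el.resistance_change(ohm, baseline).values.max()

    def test_bottom_dominates_flexion(self):
        s = noiseless_session(Movement.FLEXION, reps_per_set=2, n_sets=1)
        assert self._peak_change(s, Placement.BOTTOM_VERTICAL) > self._peak_change(
            s, Placement.TOP_VERTICAL
        )

    @pytest.mark.parametrize(
        "movement", [Movement.ANTERIOR_PELVIC_TILT, Movement.POSTERIOR_PELVIC_TILT]
    )
    def test_top_dominates_pelvic_tilt(self, movement):
        s = noiseless_session(movement, reps_per_set=2, n_sets=1)
        assert self._peak_change(s, Placement.TOP_VERTICAL) > self._peak_change(
            s, Placement.BOTTOM_VERTICAL
        )

    def test_right_diagonal_responds_before_left_in_left_rotation(self):
        s = noiseless_session(Movement.LEFT_ROTATION, reps_per_set=2, n_sets=1)

        def first_response(placement):
            stream = s.eskin_streams[placement]
            ohm = el.adu_to_resistance(stream)
            change = el.resistance_change(ohm, el.compute_baseline(ohm))
            idx = np.flatnonzero(change.values > 6.9)
            return stream.timestamps_ms[idx[0]]

        assert first_response(Placement.RIGHT_DIAGONAL) < first_response(
            Placement.LEFT_DIAGONAL
        )
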