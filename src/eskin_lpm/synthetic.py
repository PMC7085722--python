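"""Ground-truthed synthetic lumbar-pelvic movement sessions.

No raw recordings are publicly available for this kind of paired
E-Skin / reference-IMU protocol, so the pipeline is exercised on sessions
generated here.  A session emulates one participant performing the five
standard lumbar-pelvic movements (flexion, extension, anterior/posterior
pelvic tilt, left/right lateral flexion, left/right rotation), each
repeated 5 times per set over 3 sets (15 repetitions).

The generator encodes the statistical structure the analysis stages
assume:

* raised-cosine angle ramps between rest (0°) and a per-repetition peak,
  with a hold at the peak (≈10 s for flexion) and rests between reps;
* placement-dependent coupling from trunk angle to skin strain — the
  bottom vertical sensor dominates flexion, the top vertical sensor
  dominates pelvic tilt, the diagonal sensors dominate lateral flexion
  and rotation (with the contralateral sensor responding more strongly
  in lateral flexion and responding *first* in rotation);
* "transient" channels that respond to movement rate rather than angle,
  producing the double-spike signatures seen on the top sensor during
  extension and the bottom sensor during posterior pelvic tilt;
* a skin pre-stretch: the strain trajectory leads the angle trajectory
  by a configurable interval (default 1 s) because the back skin
  stretches before the trunk angle changes;
* additive baseline drift accumulating after each repetition (adhesive
  slip), Gaussian measurement noise added before 12-bit quantisation,
  and the raw-count polarity of the real device (ADU decrease on
  stretch);
* asynchronous sampling: E-Skin channels at 15 Hz, the angle channel at
  a rate drawn uniformly in 19.0-19.8 Hz.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    ConfigurationError,
    GenerationError,
    Movement,
    ParameterError,
    Placement,
    TimeSeries,
)
from .sensor import AdcParams, StrainSensorParams, strain_to_resistance

__all__ = [
    "MovementProfile",
    "SessionScript",
    "CouplingModel",
    "RepetitionTruth",
    "SyntheticSession",
    "default_profiles",
    "default_script",
    "default_coupling",
    "default_session_sensor",
    "generate_angle_trajectory",
    "angle_to_strain",
    "generate_session",
]

# Sign convention for peak angles: flexion, anterior tilt, left lateral
# flexion and left rotation positive; their opposites negative.
_POSITIVE = {
    Movement.FLEXION,
    Movement.ANTERIOR_PELVIC_TILT,
    Movement.LEFT_LATERAL_FLEXION,
    Movement.LEFT_ROTATION,
}


@dataclass
class MovementProfile:
    """One movement's trajectory template.

    ``peak_range``, when set, draws each repetition's peak uniformly from
    the given (low, high) interval instead of using ``peak_angle`` — used
    for extension, where participants rarely reach the same maximum twice.
    """

    movement: Movement
    peak_angle: float
    ramp_duration: float = 3.0
    hold_duration: float = 3.0
    rest_duration: float = 6.0
    peak_range: tuple[float, float] | None = None
    rest_jitter_s: float = 0.5  # per-rep rest lengthening drawn in [0, rest_jitter_s]

    def __post_init__(self) -> None:
        if self.ramp_duration <= 0:
            raise ParameterError("ramp_duration must be positive")
        if self.hold_duration < 0 or self.rest_duration < 0 or self.rest_jitter_s < 0:
            raise ParameterError("hold/rest durations and jitter must be non-negative")
        positive = self.movement in _POSITIVE
        if self.peak_angle != 0 and (self.peak_angle > 0) != positive:
            raise ParameterError(
                f"peak_angle sign does not match convention for {self.movement.value}"
            )

    @property
    def rep_period(self) -> float:
        """Duration of one repetition block: rest + ramp + hold + ramp."""
        return self.rest_duration + 2 * self.ramp_duration + self.hold_duration


def default_profiles() -> dict[Movement, MovementProfile]:
    """Study-condition movement templates.

    Flexion goes to 55° with a ~10 s hold; extension to around −12° with
    per-repetition peaks in [−17°, −10°].  Pelvic tilt, lateral flexion
    and rotation peaks are not quantified in the underlying protocol and
    use typical adult lumbar ranges (15°, 25°, 30°).
    """
    return {
        Movement.FLEXION: MovementProfile(Movement.FLEXION, 55.0, hold_duration=10.0),
        Movement.EXTENSION: MovementProfile(
            Movement.EXTENSION, -12.0, peak_range=(-17.0, -10.0)
        ),
        Movement.ANTERIOR_PELVIC_TILT: MovementProfile(Movement.ANTERIOR_PELVIC_TILT, 15.0),
        Movement.POSTERIOR_PELVIC_TILT: MovementProfile(Movement.POSTERIOR_PELVIC_TILT, -15.0),
        Movement.LEFT_LATERAL_FLEXION: MovementProfile(Movement.LEFT_LATERAL_FLEXION, 25.0),
        Movement.RIGHT_LATERAL_FLEXION: MovementProfile(Movement.RIGHT_LATERAL_FLEXION, -25.0),
        Movement.LEFT_ROTATION: MovementProfile(Movement.LEFT_ROTATION, 30.0),
        Movement.RIGHT_ROTATION: MovementProfile(Movement.RIGHT_ROTATION, -30.0),
    }


@dataclass
class SessionScript:
    """Ordered movement profiles and the repetition scheme (5 reps × 3 sets)."""

    profiles: list[MovementProfile]
    reps_per_set: int = 5
    n_sets: int = 3

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ParameterError("script needs at least one movement profile")
        if self.reps_per_set < 1 or self.n_sets < 1:
            raise ParameterError("reps_per_set and n_sets must be >= 1")

    @property
    def total_reps(self) -> int:
        return self.reps_per_set * self.n_sets


def default_script(movements: list[Movement] | None = None) -> SessionScript:
    profiles = default_profiles()
    if movements is None:
        movements = list(profiles)
    return SessionScript(profiles=[profiles[m] for m in movements])


@dataclass
class CouplingModel:
    """Angle → skin-strain coupling for every (movement, placement) pair.

    ``coupling`` holds the coefficient per pair; for sustained channels it
    is strain per degree (strain = coef·|angle|^exponent), for pairs in
    ``transient`` it is strain per (degree/second) applied to the angular
    rate (strain = coef·|dθ/dt|), producing one spike per ramp and hence
    the double-spike repetition signature.  ``onset_delay`` shifts a
    channel's response later in time (seconds), used to encode the
    rotation finding that the contralateral sensor rises first.
    """

    coupling: dict[tuple[Movement, Placement], float]
    nonlinearity: dict[tuple[Movement, Placement], float] = field(default_factory=dict)
    transient: set[tuple[Movement, Placement]] = field(default_factory=set)
    onset_delay: dict[tuple[Movement, Placement], float] = field(default_factory=dict)
    max_strain: float = 1.0

    def __post_init__(self) -> None:
        for key, coef in self.coupling.items():
            if not np.isfinite(coef):
                raise ParameterError(f"non-finite coupling coefficient for {key}")
        for key, exp in self.nonlinearity.items():
            if exp <= 0:
                raise ParameterError(f"nonlinearity exponent must be positive for {key}")

    def coefficient(self, movement: Movement, placement: Placement) -> float:
        key = (movement, placement)
        if key not in self.coupling:
            raise ConfigurationError(f"no coupling defined for {movement.value}/{placement.value}")
        return self.coupling[key]

    def exponent(self, movement: Movement, placement: Placement) -> float:
        return self.nonlinearity.get((movement, placement), 1.0)

    def is_transient(self, movement: Movement, placement: Placement) -> bool:
        return (movement, placement) in self.transient

    def delay(self, movement: Movement, placement: Placement) -> float:
        return self.onset_delay.get((movement, placement), 0.0)


def default_coupling() -> CouplingModel:
    """Default coupling encoding the placement findings.

    Sagittal movements load the vertical sensors (bottom dominates
    flexion, top dominates pelvic tilt, extension is nonlinear on the
    bottom with a rate-transient top), coronal/transverse movements load
    the diagonal sensors (contralateral larger in lateral flexion,
    near-equal with a delayed ipsilateral channel in rotation).  The
    diagonal channels are decoupled from sagittal movements and vice
    versa.  Coefficients are sized so that 55° flexion produces ~0.30
    peak strain on the bottom sensor.
    """
    M, P = Movement, Placement
    coupling: dict[tuple[Movement, Placement], float] = {
        (m, p): 0.0 for m in Movement for p in Placement
    }
    coupling.update(
        {
            (M.FLEXION, P.BOTTOM_VERTICAL): 0.30 / 55.0,
            (M.FLEXION, P.TOP_VERTICAL): 0.0028,
            (M.EXTENSION, P.BOTTOM_VERTICAL): 0.0037,  # with exponent 1.4: ~0.12 at 12 deg
            (M.EXTENSION, P.TOP_VERTICAL): 0.0286,  # transient: ~0.18 peak at 12 deg / 3 s ramp
            (M.ANTERIOR_PELVIC_TILT, P.TOP_VERTICAL): 0.013,
            (M.ANTERIOR_PELVIC_TILT, P.BOTTOM_VERTICAL): 0.0005,
            (M.POSTERIOR_PELVIC_TILT, P.TOP_VERTICAL): 0.013,
            (M.POSTERIOR_PELVIC_TILT, P.BOTTOM_VERTICAL): 0.0102,  # transient double spike
            (M.LEFT_LATERAL_FLEXION, P.RIGHT_DIAGONAL): 0.009,
            (M.LEFT_LATERAL_FLEXION, P.LEFT_DIAGONAL): 0.005,
            (M.RIGHT_LATERAL_FLEXION, P.LEFT_DIAGONAL): 0.009,
            (M.RIGHT_LATERAL_FLEXION, P.RIGHT_DIAGONAL): 0.005,
            (M.LEFT_ROTATION, P.RIGHT_DIAGONAL): 0.007,
            (M.LEFT_ROTATION, P.LEFT_DIAGONAL): 0.0065,
            (M.RIGHT_ROTATION, P.LEFT_DIAGONAL): 0.007,
            (M.RIGHT_ROTATION, P.RIGHT_DIAGONAL): 0.0065,
        }
    )
    return CouplingModel(
        coupling=coupling,
        nonlinearity={(M.EXTENSION, P.BOTTOM_VERTICAL): 1.4},
        transient={
            (M.EXTENSION, P.TOP_VERTICAL),
            (M.POSTERIOR_PELVIC_TILT, P.BOTTOM_VERTICAL),
        },
        onset_delay={
            (M.LEFT_ROTATION, P.LEFT_DIAGONAL): 1.5,
            (M.RIGHT_ROTATION, P.RIGHT_DIAGONAL): 1.5,
        },
    )


def default_session_sensor() -> StrainSensorParams:
    """Device parameters for simulated sessions.

    R0 = 1400 Ω reproduces the resistance-change scale of the real
    recordings: with GF 0.309 and ~0.30 peak strain at 55° flexion the
    peak resistance change is ~130 Ω, which places the 6.9 Ω onset
    threshold at the same relative depth as the 3° threshold on a 55°
    flexion.  Drift of 0.25 Ω per repetition keeps the accumulated rest
    offset over 15 repetitions below the onset threshold.
    """
    return StrainSensorParams(r0=1400.0, drift_per_rep=0.25)


def _rep_schedule(
    profile: MovementProfile, n_reps: int, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-rep rest durations and block start times within a segment.

    A repetition block is rest + ramp + hold + ramp.  Rests are lengthened
    by a uniform draw in [0, rest_jitter_s] because participants cannot
    reproduce their timing exactly from repetition to repetition; without
    this the exactly periodic blocks would alias against the 1-s analysis
    bins.  Returns (rests, block_starts), both in seconds relative to the
    segment start.
    """
    if rng is not None and profile.rest_jitter_s > 0:
        offsets = rng.uniform(0.0, profile.rest_jitter_s, size=n_reps)
    else:
        offsets = np.zeros(n_reps)
    rests = profile.rest_duration + offsets
    blocks = rests + 2 * profile.ramp_duration + profile.hold_duration
    starts = np.concatenate([[0.0], np.cumsum(blocks)[:-1]])
    return rests, starts


def _segment_duration(profile: MovementProfile, rests: np.ndarray) -> float:
    """Segment span: all repetition blocks plus a trailing rest."""
    blocks = rests + 2 * profile.ramp_duration + profile.hold_duration
    return float(np.sum(blocks) + profile.rest_duration)


def _profile_angle_and_rate(
    profile: MovementProfile,
    peaks: np.ndarray,
    rests: np.ndarray,
    starts: np.ndarray,
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Angle (deg) and angular rate (deg/s) of a movement segment at times t.

    t is in seconds relative to the segment start; outside the segment's
    repetitions the angle is 0 (rest).
    """
    n_reps = len(peaks)
    ramp, hold = profile.ramp_duration, profile.hold_duration
    angle = np.zeros_like(t)
    rate = np.zeros_like(t)
    rep = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, n_reps - 1)
    u = t - starts[rep] - rests[rep]  # time into the active part of the block
    peak = peaks[rep]

    up = (u >= 0) & (u < ramp)
    angle[up] = peak[up] * 0.5 * (1 - np.cos(np.pi * u[up] / ramp))
    rate[up] = peak[up] * 0.5 * np.pi / ramp * np.sin(np.pi * u[up] / ramp)

    flat = (u >= ramp) & (u < ramp + hold)
    angle[flat] = peak[flat]

    v = u - ramp - hold
    down = (v >= 0) & (v < ramp)
    angle[down] = peak[down] * 0.5 * (1 + np.cos(np.pi * v[down] / ramp))
    rate[down] = -peak[down] * 0.5 * np.pi / ramp * np.sin(np.pi * v[down] / ramp)
    return angle, rate


def _draw_peaks(
    profile: MovementProfile, n_reps: int, rng: np.random.Generator | None
) -> np.ndarray:
    if profile.peak_range is not None and rng is not None:
        lo, hi = profile.peak_range
        return rng.uniform(lo, hi, size=n_reps)
    return np.full(n_reps, profile.peak_angle)


def generate_angle_trajectory(
    profile: MovementProfile,
    n_reps: int,
    rate_hz: float,
    seed: int | None = None,
) -> TimeSeries:
    """Noise-free reference angle trajectory for ``n_reps`` repetitions.

    Each repetition is rest at 0°, a raised-cosine ramp to the peak, a
    hold, a ramp back and a trailing rest.  When ``seed`` is given and
    the profile defines a ``peak_range``, per-repetition peaks are drawn
    from it.
    """
    if rate_hz <= 0:
        raise ParameterError("rate_hz must be positive")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    rng = np.random.default_rng(seed) if seed is not None else None
    peaks = _draw_peaks(profile, n_reps, rng)
    rests, starts = _rep_schedule(profile, n_reps, rng)
    duration = _segment_duration(profile, rests)
    t = np.arange(0.0, duration, 1.0 / rate_hz)
    angle, _ = _profile_angle_and_rate(profile, peaks, rests, starts, t)
    return TimeSeries(t * 1000.0, angle, unit="degree", channel="angle")


def angle_to_strain(
    angle: TimeSeries,
    coupling: CouplingModel,
    movement: Movement,
    placement: Placement,
) -> TimeSeries:
    """Map an angle series to skin strain for one sensor placement.

    Sustained channels follow strain = clamp(coef·|θ|^exponent, 0,
    max_strain); transient channels respond to the angular rate,
    strain = clamp(coef·|dθ/dt|, 0, max_strain), with the rate estimated
    numerically from the series.  A zero coefficient yields zero strain.
    """
    coef = coupling.coefficient(movement, placement)
    if coupling.is_transient(movement, placement):
        t_s = angle.timestamps_ms / 1000.0
        if len(angle) < 2:
            raw = np.zeros(len(angle))
        else:
            raw = coef * np.abs(np.gradient(angle.values, t_s))
    else:
        raw = coef * np.abs(angle.values) ** coupling.exponent(movement, placement)
    strain = np.clip(raw, 0.0, coupling.max_strain)
    return angle.with_values(strain, unit="strain")


@dataclass
class RepetitionTruth:
    """Ground truth for one repetition within a session."""

    rep_id: int
    movement: Movement
    start_ms: float
    end_ms: float
    skin_onset_ms: float
    angle_onset_ms: float
    peak_deg: float


@dataclass
class SyntheticSession:
    """Paired E-Skin (ADU) and reference angle (degree) streams + truth."""

    eskin_streams: dict[Placement, TimeSeries]
    angle_stream: TimeSeries
    truth: list[RepetitionTruth]
    seed: int
    sensor: StrainSensorParams
    adc: AdcParams
    rest_resistance: float
    angle_rate_hz: float

    def truth_for(self, movement: Movement) -> list[RepetitionTruth]:
        return [r for r in self.truth if r.movement == movement]

    def equals(self, other: "SyntheticSession") -> bool:
        return (
            self.angle_stream.equals(other.angle_stream)
            and set(self.eskin_streams) == set(other.eskin_streams)
            and all(s.equals(other.eskin_streams[p]) for p, s in self.eskin_streams.items())
            and self.truth == other.truth
        )


def generate_session(
    script: SessionScript | None = None,
    coupling: CouplingModel | None = None,
    sensor: StrainSensorParams | None = None,
    *,
    adc: AdcParams | None = None,
    eskin_rate_hz: float = 15.0,
    angle_rate_range: tuple[float, float] = (19.0, 19.8),
    angle_rate_hz: float | None = None,
    noise_sd_adu: float = 2.0,
    angle_noise_sd_deg: float = 0.3,
    onset_lead_s: float = 1.0,
    rest_resistance: float = 330.0,
    placements: list[Placement] | None = None,
    quantize: bool = True,
    seed: int = 0,
) -> SyntheticSession:
    """Generate one fully ground-truthed paired session.

    The E-Skin strain trajectory leads the angle trajectory by
    ``onset_lead_s`` (skin pre-stretch).  ``rest_resistance`` is the
    unstrained resistance presented to the ADC; stretching *increases*
    sensor resistance but the emitted raw ADU reading *decreases*,
    matching the real device's polarity.  Gaussian noise of
    ``noise_sd_adu`` counts is added before quantisation.  All randomness
    derives from ``seed``.
    """
    script = script or default_script()
    coupling = coupling or default_coupling()
    sensor = sensor or default_session_sensor()
    adc = adc or AdcParams()
    placements = placements or list(Placement)
    if eskin_rate_hz <= 0:
        raise GenerationError("eskin_rate_hz must be positive")
    if onset_lead_s < 0:
        raise GenerationError("onset_lead_s must be non-negative")
    max_delta_r = rest_resistance
    rng = np.random.default_rng(seed)
    angle_rate = (
        float(angle_rate_hz)
        if angle_rate_hz is not None
        else float(rng.uniform(*angle_rate_range))
    )
    if angle_rate <= 0:
        raise GenerationError("angle rate must be positive")

    n_reps = script.total_reps
    peaks_per_segment = []
    schedule_per_segment = []
    for p in script.profiles:
        peaks_per_segment.append(_draw_peaks(p, n_reps, rng))
        schedule_per_segment.append(_rep_schedule(p, n_reps, rng))
    seg_durations = [
        _segment_duration(p, rests)
        for p, (rests, _) in zip(script.profiles, schedule_per_segment)
    ]
    seg_starts = np.concatenate([[0.0], np.cumsum(seg_durations)[:-1]])
    duration = float(np.sum(seg_durations))

    t_angle = np.arange(0.0, duration, 1.0 / angle_rate)
    t_eskin = np.arange(0.0, duration, 1.0 / eskin_rate_hz)

    # reference angle channel
    angle_vals = np.zeros_like(t_angle)
    for prof, peaks, (rests, starts), start in zip(
        script.profiles, peaks_per_segment, schedule_per_segment, seg_starts
    ):
        a, _ = _profile_angle_and_rate(prof, peaks, rests, starts, t_angle - start)
        angle_vals += a
    if angle_noise_sd_deg > 0:
        angle_vals = angle_vals + rng.normal(0.0, angle_noise_sd_deg, size=angle_vals.shape)
    angle_stream = TimeSeries(t_angle * 1000.0, angle_vals, unit="degree", channel="angle")

    # ground truth and rep-completion times (for drift accumulation)
    truth: list[RepetitionTruth] = []
    completions: list[float] = []
    rep_id = 0
    for prof, peaks, (rests, starts), seg_start in zip(
        script.profiles, peaks_per_segment, schedule_per_segment, seg_starts
    ):
        active = 2 * prof.ramp_duration + prof.hold_duration
        for i in range(n_reps):
            block = seg_start + starts[i]
            block_end = block + rests[i] + active
            angle_onset = block + rests[i]
            truth.append(
                RepetitionTruth(
                    rep_id=rep_id,
                    movement=prof.movement,
                    start_ms=block * 1000.0,
                    end_ms=block_end * 1000.0,
                    skin_onset_ms=(angle_onset - onset_lead_s) * 1000.0,
                    angle_onset_ms=angle_onset * 1000.0,
                    peak_deg=float(peaks[i]),
                )
            )
            completions.append(block_end)
            rep_id += 1
    completions_arr = np.asarray(completions)

    # E-Skin channels: strain (lead-shifted) -> resistance -> drift -> raw ADU
    eskin_streams: dict[Placement, TimeSeries] = {}
    reps_done = (t_eskin[:, None] >= completions_arr[None, :]).sum(axis=1)
    drift = sensor.drift_per_rep * reps_done
    for placement in placements:
        strain = np.zeros_like(t_eskin)
        for prof, peaks, (rests, starts), seg_start in zip(
            script.profiles, peaks_per_segment, schedule_per_segment, seg_starts
        ):
            delay = coupling.delay(prof.movement, placement)
            t_local = t_eskin - seg_start + onset_lead_s - delay
            a, r = _profile_angle_and_rate(prof, peaks, rests, starts, t_local)
            coef = coupling.coefficient(prof.movement, placement)
            if coupling.is_transient(prof.movement, placement):
                strain += coef * np.abs(r)
            else:
                exp = coupling.exponent(prof.movement, placement)
                strain += coef * np.abs(a) ** exp
        strain = np.clip(strain, 0.0, min(coupling.max_strain, sensor.max_strain))
        resistance = np.asarray(strain_to_resistance(strain, sensor))
        if sensor.noise_sd > 0:
            resistance = resistance + rng.normal(0.0, sensor.noise_sd, size=resistance.shape)
        delta_r = resistance - sensor.r0 + drift
        if np.any(delta_r > max_delta_r):
            raise GenerationError(
                f"resistance change exceeds rest reading ({max_delta_r} ohm) on "
                f"{placement.value}; lower the coupling or raise rest_resistance"
            )
        reading = rest_resistance - delta_r  # stretch -> lower reading -> lower ADU
        adu = reading * adc.current / adc.v_ref * adc.full_scale
        if noise_sd_adu > 0:
            adu = adu + rng.normal(0.0, noise_sd_adu, size=adu.shape)
        if quantize:
            adu = np.floor(adu + 0.5)
        adu = np.clip(adu, 0, adc.full_scale)
        eskin_streams[placement] = TimeSeries(
            t_eskin * 1000.0, adu, unit="ADU", channel=placement.value
        )

    return SyntheticSession(
        eskin_streams=eskin_streams,
        angle_stream=angle_stream,
        truth=truth,
        seed=seed,
        sensor=sensor,
        adc=adc,
        rest_resistance=rest_resistance,
        angle_rate_hz=angle_rate,
    )
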