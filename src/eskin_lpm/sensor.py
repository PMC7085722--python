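"""Forward device model of the piezoresistive E-Skin strain sensor.

The sensor is a graphite-microflake strain gauge whose resistance grows
with applied strain.  Its sensitivity is piecewise: the gauge factor
GF = (ΔR/R0)/ε is 0.309 below 30 % strain and 0.122 from 30 % to 100 %,
so the forward model is a continuous piecewise-linear map

    R(ε) = R0 (1 + gf_low·ε)                              for ε ≤ b
    R(ε) = R0 (1 + gf_low·b + gf_high·(ε − b))            for ε > b

with breakpoint b = 0.30.  A 12-bit ADC digitises the voltage over the
sensor at a constant 5 mA supply against a 3.3 V reference, so resistance
and raw counts are related linearly with 4096 ADU ↔ 660 Ω.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InsufficientDataError, ParameterError, RangeError, TimeSeries

__all__ = [
    "StrainSensorParams",
    "AdcParams",
    "GaugeEstimate",
    "CyclicTestResult",
    "strain_to_resistance",
    "resistance_to_adu",
    "estimate_gauge_factor",
    "simulate_cyclic_test",
]


@dataclass
class StrainSensorParams:
    """Piecewise gauge-factor device model plus noise/drift parameters.

    ``r0`` is the unstrained resistance in ohms; the manufacturer-style
    characterisation default is 100 Ω.  ``noise_sd`` (ohms) and
    ``drift_per_rep`` (ohms added to the rest level after each movement
    repetition, emulating adhesive slip) are only applied by the session
    generator, never by the deterministic forward map itself.
    """

    r0: float = 100.0
    gf_low: float = 0.309
    gf_high: float = 0.122
    breakpoint: float = 0.30
    max_strain: float = 1.00
    noise_sd: float = 0.0
    drift_per_rep: float = 0.0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ParameterError("r0 must be positive")
        if not (0 < self.breakpoint < self.max_strain <= 1.0):
            raise ParameterError("require 0 < breakpoint < max_strain <= 1.0")
        if self.gf_low < 0 or self.gf_high < 0:
            raise ParameterError("gauge factors must be non-negative")
        if self.noise_sd < 0 or self.drift_per_rep < 0:
            raise ParameterError("noise_sd and drift_per_rep must be non-negative")


@dataclass
class AdcParams:
    """12-bit ADC operating point: 4096 counts ↔ 3.3 V at 5 mA supply."""

    full_scale: int = 4096
    v_ref: float = 3.3
    current: float = 0.005

    def __post_init__(self) -> None:
        if self.full_scale <= 0 or self.v_ref <= 0 or self.current <= 0:
            raise ParameterError("full_scale, v_ref and current must be positive")

    @property
    def ohms_per_adu(self) -> float:
        """Resistance quantum of one count: v_ref / (full_scale · current)."""
        return self.v_ref / (self.full_scale * self.current)


@dataclass
class GaugeEstimate:
    """Fitted gauge factor over a strain range, with residual sum of squares."""

    gf: float
    strain_range: tuple[float, float]
    residual: float
    n_points: int


def _resistance_of_strain(strain: np.ndarray, params: StrainSensorParams) -> np.ndarray:
    b = params.breakpoint
    low = params.r0 * (1.0 + params.gf_low * strain)
    high = params.r0 * (1.0 + params.gf_low * b + params.gf_high * (strain - b))
    return np.where(strain <= b, low, high)


def strain_to_resistance(
    strain: TimeSeries | np.ndarray,
    params: StrainSensorParams,
    rng: np.random.Generator | None = None,
) -> TimeSeries | np.ndarray:
    """Map strain to resistance through the piecewise gauge-factor model.

    Strain must lie in ``[0, max_strain]``.  Gaussian resistance noise of
    sd ``params.noise_sd`` ohms is added only when an ``rng`` is supplied.
    Accepts either a :class:`TimeSeries` (unit ``strain``) or a bare array
    and returns the matching type (unit ``ohm``).
    """
    values = strain.values if isinstance(strain, TimeSeries) else np.asarray(strain, dtype=float)
    if np.any(values < -1e-12) or np.any(values > params.max_strain + 1e-12):
        raise RangeError(
            f"strain outside [0, {params.max_strain}]: "
            f"range [{values.min():.4f}, {values.max():.4f}]"
        )
    r = _resistance_of_strain(np.clip(values, 0.0, params.max_strain), params)
    if rng is not None and params.noise_sd > 0:
        r = r + rng.normal(0.0, params.noise_sd, size=r.shape)
    if isinstance(strain, TimeSeries):
        return strain.with_values(r, unit="ohm")
    return r


def resistance_to_adu(
    resistance: TimeSeries | np.ndarray | float,
    adc: AdcParams | None = None,
    quantize: bool = True,
) -> TimeSeries | np.ndarray | float:
    """Digitise resistance to counts: X = round(Y·I/V_ref·full_scale).

    Rounding is half-up and the result is clamped to ``[0, full_scale]``
    (clamping is the contract — no error on overrange).  ``quantize=False``
    skips rounding, useful for idealised noiseless studies.
    """
    adc = adc or AdcParams()
    scalar = np.isscalar(resistance)
    values = (
        resistance.values
        if isinstance(resistance, TimeSeries)
        else np.asarray(resistance, dtype=float)
    )
    if np.any(values < 0):
        raise RangeError("resistance must be non-negative")
    x = values * adc.current / adc.v_ref * adc.full_scale
    if quantize:
        x = np.floor(x + 0.5)  # round half-up: deterministic 12-bit behaviour
    x = np.clip(x, 0, adc.full_scale)
    if isinstance(resistance, TimeSeries):
        return resistance.with_values(x, unit="ADU")
    return float(x) if scalar else x


def estimate_gauge_factor(
    strains: np.ndarray,
    resistances: np.ndarray,
    r0: float,
    strain_range: tuple[float, float],
) -> GaugeEstimate:
    """Estimate the gauge factor GF = d[(R−R0)/R0]/dε over a strain range.

    Fits the relative resistance change against strain by least squares
    over the points inside ``strain_range`` (inclusive) and reports the
    slope.  The intercept is left free so the estimator returns the
    incremental sensitivity of each regime: above the breakpoint the
    relative-resistance curve is offset by the low-strain contribution and
    a through-origin fit would bias the slope.
    """
    if r0 <= 0:
        raise ParameterError("r0 must be positive")
    lo, hi = strain_range
    if not lo < hi:
        raise ParameterError("strain_range must satisfy low < high")
    strains = np.asarray(strains, dtype=float)
    resistances = np.asarray(resistances, dtype=float)
    mask = (strains >= lo - 1e-12) & (strains <= hi + 1e-12)
    eps = strains[mask]
    rel = (resistances[mask] - r0) / r0
    if len(eps) < 2:
        raise InsufficientDataError(
            f"need at least 2 points in strain range [{lo}, {hi}], got {len(eps)}"
        )
    # slope of rel vs eps, free intercept
    x = eps - eps.mean()
    y = rel - rel.mean()
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise InsufficientDataError("all selected strains identical")
    gf = float(np.dot(x, y) / sxx)
    resid = y - gf * x
    return GaugeEstimate(
        gf=gf, strain_range=(lo, hi), residual=float(np.dot(resid, resid)), n_points=len(eps)
    )


@dataclass
class CyclicTestResult:
    """Outcome of a durability (cyclic strain) simulation."""

    series: TimeSeries  # resistance trace, ohms
    cycle_peaks: np.ndarray  # per-cycle peak resistance, ohms
    peak_variation: float  # relative (max−min)/mean over the final 10 % of cycles
    settled: bool  # peak_variation < 1 %
    released_resistance: float  # resistance at zero strain after the last cycle


def simulate_cyclic_test(
    params: StrainSensorParams,
    n_cycles: int = 1000,
    strain_level: float = 0.30,
    freq_hz: float = 0.4,
    samples_per_cycle: int = 20,
    stabilization_amplitude: float = 0.02,
    stabilization_tau_cycles: float = 150.0,
) -> CyclicTestResult:
    """Simulate a triangular-wave durability test of ``n_cycles`` cycles.

    Fresh sensors show a slight early-cycle fluctuation before settling;
    this is modelled as a multiplicative perturbation of the resistance
    *change* that decays exponentially with cycle index
    (``amplitude · exp(−cycle/tau)``), so the released (zero-strain)
    resistance always returns exactly to R0.  The summary reports the
    relative peak variation over the final 10 % of cycles and whether the
    sensor has settled (< 1 % variation).
    """
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    if not (0 < strain_level <= params.max_strain):
        raise ParameterError("strain_level must lie in (0, max_strain]")
    n = n_cycles * samples_per_cycle
    t = np.arange(n) / (samples_per_cycle * freq_hz)  # seconds
    phase = (np.arange(n) % samples_per_cycle) / samples_per_cycle
    strain = strain_level * (1.0 - np.abs(2.0 * phase - 1.0))  # triangular 0→level→0
    cycle_idx = np.arange(n) // samples_per_cycle
    base = _resistance_of_strain(strain, params)
    transient = 1.0 + stabilization_amplitude * np.exp(-cycle_idx / stabilization_tau_cycles)
    r = params.r0 + (base - params.r0) * transient
    series = TimeSeries(t * 1000.0, r, unit="ohm", channel="cyclic_test")
    peaks = r.reshape(n_cycles, samples_per_cycle).max(axis=1)
    tail = peaks[-max(1, n_cycles // 10):]
    variation = float((tail.max() - tail.min()) / tail.mean()) if tail.mean() != 0 else 0.0
    released = float(
        params.r0
        + (_resistance_of_strain(np.array([0.0]), params)[0] - params.r0)
        * (1.0 + stabilization_amplitude * np.exp(-(n_cycles - 1) / stabilization_tau_cycles))
    )
    return CyclicTestResult(
        series=series,
        cycle_peaks=peaks,
        peak_variation=variation,
        settled=variation < 0.01,
        released_resistance=released,
    )
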