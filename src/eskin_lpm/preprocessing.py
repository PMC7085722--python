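"""Smoothing, baselining, unit conversion and per-second alignment.

Raw E-Skin counts are smoothed with the same scalar Kalman recurrence the
acquisition app uses, converted to ohms through the ADC relation
Y = X/4096 × 3.3 ÷ 0.005, referenced to a 5-s static-standing baseline,
and expressed as a resistance *change* that is positive when the skin
stretches (the raw count polarity — counts fall on stretch — is folded in
here, so downstream stages never see it).  Because the E-Skin (~15 Hz)
and the reference angle channel (~19-20 Hz) sample asynchronously, both
are reduced to per-second means and inner-joined on the second label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AlignmentError,
    InsufficientDataError,
    ParameterError,
    Placement,
    RangeError,
    TimeSeries,
)
from .sensor import AdcParams

logger = logging.getLogger(__name__)

__all__ = [
    "KalmanParams",
    "AlignedPair",
    "kalman_smooth",
    "compute_baseline",
    "adu_to_resistance",
    "resistance_change",
    "downsample_per_second",
    "align_streams",
    "preprocess_session",
]


@dataclass
class KalmanParams:
    """Scalar Kalman smoother initial conditions.

    ``r`` is the measurement uncertainty, ``p`` the (evolving) estimate
    uncertainty and ``q`` the process variance; the defaults (4, 4, 0.05)
    are the values used on-device.  The gain k = p/(p+r) is derived each
    step.
    """

    r: float = 4.0
    p: float = 4.0
    q: float = 0.05

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ParameterError("measurement uncertainty r must be positive")
        if self.p < 0 or self.q < 0:
            raise ParameterError("p and q must be non-negative")


def kalman_smooth(series: TimeSeries, params: KalmanParams | None = None) -> TimeSeries:
    """Smooth a series with the scalar Kalman recurrence.

    Per sample: k = p/(p+r); estimate ← last + k·(measurement − last);
    p ← (1−k)·p + |last − current|·q.  The first estimate is initialised
    to the first measurement, so a constant input is a fixed point.
    """
    params = params or KalmanParams()
    if len(series) == 0:
        raise InsufficientDataError("cannot smooth an empty series")
    values = series.values
    out = np.empty_like(values)
    p = params.p
    r = params.r
    q = params.q
    last = values[0]
    out[0] = last
    for i in range(1, len(values)):
        k = p / (p + r)
        current = last + k * (values[i] - last)
        p = (1.0 - k) * p + abs(last - current) * q
        out[i] = current
        last = current
    return series.with_values(out)


def compute_baseline(series: TimeSeries, window_s: float = 5.0, offset_s: float = 0.0) -> float:
    """Mean of the samples in the static window at the start of a recording.

    Averages every sample with timestamp in
    [start + offset_s, start + offset_s + window_s); the recording is
    assumed to begin in a static standing position.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    # the series must cover the window; one nominal sample period of slack so
    # that e.g. 75 samples at 15 Hz count as covering [0, 5) s
    dt_s = float(np.median(np.diff(series.timestamps_ms))) / 1000.0 if len(series) > 1 else 0.0
    if len(series) == 0 or series.duration_s + dt_s < offset_s + window_s:
        raise InsufficientDataError(
            f"series spans {series.duration_s:.2f}s; need {offset_s + window_s:.2f}s "
            f"for the baseline window"
        )
    start = series.timestamps_ms[0] + offset_s * 1000.0
    mask = (series.timestamps_ms >= start) & (series.timestamps_ms < start + window_s * 1000.0)
    if not np.any(mask):
        raise InsufficientDataError("no samples fall inside the baseline window")
    return float(series.values[mask].mean())


def adu_to_resistance(
    adu: TimeSeries | np.ndarray | float, adc: AdcParams | None = None
) -> TimeSeries | np.ndarray | float:
    """Convert raw counts to ohms: Y = X / full_scale × v_ref ÷ current."""
    adc = adc or AdcParams()
    scalar = np.isscalar(adu)
    values = adu.values if isinstance(adu, TimeSeries) else np.asarray(adu, dtype=float)
    if np.any(values < 0) or np.any(values > adc.full_scale):
        raise RangeError(f"ADU outside [0, {adc.full_scale}]")
    y = values / adc.full_scale * adc.v_ref / adc.current
    if isinstance(adu, TimeSeries):
        return adu.with_values(y, unit="ohm")
    return float(y) if scalar else y


def resistance_change(series: TimeSeries, baseline: float) -> TimeSeries:
    """Resistance change relative to baseline, positive on stretch.

    With the raw-count polarity (counts — hence converted ohm readings —
    fall when the sensor stretches), change(t) = baseline − Y(t) is zero
    at rest and positive during movement.
    """
    return series.with_values(baseline - series.values, unit="ohm")


def downsample_per_second(
    series: TimeSeries, return_counts: bool = False
) -> TimeSeries | tuple[TimeSeries, np.ndarray]:
    """Average samples into half-open 1-s bins [s, s+1).

    Bin label = floor(timestamp_ms / 1000); one mean per non-empty bin,
    timestamped at the bin label.  Empty bins are never fabricated.
    """
    if len(series) == 0:
        raise InsufficientDataError("cannot downsample an empty series")
    bins = np.floor_divide(series.timestamps_ms, 1000.0).astype(np.int64)
    grouped = pd.Series(series.values).groupby(bins)
    means = grouped.mean()
    out = TimeSeries(
        means.index.to_numpy(dtype=float) * 1000.0,
        means.to_numpy(),
        unit=series.unit,
        channel=series.channel,
    )
    if return_counts:
        return out, grouped.count().to_numpy()
    return out


@dataclass
class AlignedPair:
    """Per-second E-Skin and angle values on a shared second grid."""

    seconds: np.ndarray  # integer second-bin labels
    eskin_values: dict[str, np.ndarray]  # channel label -> per-second means
    angle_values: np.ndarray
    counts: dict[str, np.ndarray] = field(default_factory=dict)
    dropped_bins: int = 0

    def __len__(self) -> int:
        return len(self.seconds)


def align_streams(
    eskin: dict[str, TimeSeries],
    angle: TimeSeries,
    counts: dict[str, np.ndarray] | None = None,
) -> AlignedPair:
    """Inner-join per-second streams on their second labels.

    All inputs must already be at 1 Hz (one sample per second bin).
    Bins missing from any channel are dropped; the drop count is logged.
    """
    frames = {name: s for name, s in eskin.items()}
    frames["__angle__"] = angle
    label_sets = []
    tables = {}
    for name, s in frames.items():
        secs = np.floor_divide(s.timestamps_ms, 1000.0).astype(np.int64)
        tables[name] = pd.Series(s.values, index=secs)
        label_sets.append(set(secs.tolist()))
    common = sorted(set.intersection(*label_sets))
    if not common:
        raise AlignmentError("streams share no common second bins")
    total = len(set.union(*label_sets))
    dropped = total - len(common)
    if dropped:
        logger.info("align_streams: dropped %d second bins missing from some channel", dropped)
    idx = np.asarray(common, dtype=np.int64)
    eskin_values = {name: tables[name].loc[idx].to_numpy() for name in eskin}
    angle_values = tables["__angle__"].loc[idx].to_numpy()
    out_counts = {}
    if counts:
        # counts were computed per original bin; re-index onto the joined grid
        for name, s in eskin.items():
            secs = np.floor_divide(s.timestamps_ms, 1000.0).astype(np.int64)
            cs = pd.Series(counts.get(name, np.ones(len(s))), index=secs)
            out_counts[name] = cs.loc[idx].to_numpy()
    return AlignedPair(
        seconds=idx,
        eskin_values=eskin_values,
        angle_values=angle_values,
        counts=out_counts,
        dropped_bins=dropped,
    )


def preprocess_session(
    eskin_streams: dict[Placement, TimeSeries] | dict[str, TimeSeries],
    angle_stream: TimeSeries,
    *,
    kalman: KalmanParams | None = None,
    smooth: bool = True,
    smooth_angle: bool = False,
    baseline_window_s: float = 5.0,
    adc: AdcParams | None = None,
) -> AlignedPair:
    """Full preprocessing chain for one session.

    Per E-Skin channel: Kalman-smooth the raw counts (mirroring the
    acquisition app; disable with ``smooth=False``), convert to ohms,
    reference to the first ``baseline_window_s`` seconds and express as a
    positive-on-stretch resistance change, then average per second.  The
    angle channel is averaged per second (and optionally smoothed).  The
    result is the inner join of all channels on the second grid.
    """
    adc = adc or AdcParams()
    per_second: dict[str, TimeSeries] = {}
    counts: dict[str, np.ndarray] = {}
    for key, stream in eskin_streams.items():
        name = key.value if isinstance(key, Placement) else str(key)
        s = kalman_smooth(stream, kalman) if smooth else stream
        ohms = adu_to_resistance(s, adc)
        baseline = compute_baseline(ohms, window_s=baseline_window_s)
        change = resistance_change(ohms, baseline)
        per_second[name], counts[name] = downsample_per_second(change, return_counts=True)
    a = kalman_smooth(angle_stream, kalman) if smooth_angle else angle_stream
    angle_1hz = downsample_per_second(a)
    return align_streams(per_second, angle_1hz, counts=counts)
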