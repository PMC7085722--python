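"""Movement onset detection and rule-based movement classification.

Onsets are detected by threshold crossing: the reference angle channel
uses a ±3° band and the E-Skin resistance-change channels a ±6.9 Ω band
around the rest level.  Because the back skin stretches before the trunk
angle changes, the E-Skin onset precedes the angle onset; the mean paired
difference (angle − E-Skin, positive when the E-Skin leads) is the
response-time difference, ~1 s for flexion in the original protocol.

Classification is deliberately rule based.  A repetition's per-channel
response pattern identifies the movement:

* diagonal channels dominant + left/right magnitude asymmetry
  → lateral flexion towards the weaker (ipsilateral) side;
* diagonal channels dominant + near-equal magnitudes with ordered onsets
  → rotation towards the side opposite the leading channel;
* bottom vertical dominant, sustained → flexion;
* top vertical dominant, sustained → pelvic tilt (posterior when the
  bottom channel shows its double-spike signature, anterior when the
  bottom channel is quiet);
* top vertical spiky (two spikes per repetition, at the start and end)
  → extension;
* no channel active → static.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import PairingError, ParameterError, Placement, STATIC, TimeSeries

__all__ = [
    "DetectionThresholds",
    "OnsetEvent",
    "MovementLabel",
    "detect_onsets",
    "response_time_difference",
    "classify_movement",
]


@dataclass
class DetectionThresholds:
    """Onset thresholds: ±3° on the angle, ±6.9 Ω on resistance change."""

    angle_deg: float = 3.0
    resistance_ohm: float = 6.9

    def __post_init__(self) -> None:
        if self.angle_deg <= 0 or self.resistance_ohm <= 0:
            raise ParameterError("thresholds must be positive")


@dataclass
class OnsetEvent:
    """A detected movement start on one channel."""

    channel: str
    onset_time_s: float
    direction: int  # sign of the excursion at the crossing
    rep_id: int | None = None


def detect_onsets(
    series: TimeSeries,
    rest_level: float,
    threshold: float,
    refractory_s: float = 3.0,
) -> list[OnsetEvent]:
    """First-crossing onset detector with a refractory period.

    The first sample with |value − rest_level| > threshold after a
    sub-threshold stretch opens an event; further crossings within
    ``refractory_s`` of the last event are suppressed, and the detector
    re-arms only once the signal has returned inside the band.  A series
    that never leaves the band yields an empty list.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    t_s = series.timestamps_ms / 1000.0
    dev = series.values - rest_level
    events: list[OnsetEvent] = []
    armed = True
    last_event = -np.inf
    for i in range(len(series)):
        outside = abs(dev[i]) > threshold
        if outside:
            if armed and t_s[i] - last_event >= refractory_s:
                events.append(
                    OnsetEvent(
                        channel=series.channel,
                        onset_time_s=float(t_s[i]),
                        direction=int(np.sign(dev[i])),
                    )
                )
                last_event = t_s[i]
            armed = False  # an ongoing excursion never re-opens an event
        else:
            armed = True
    return events


def response_time_difference(
    eskin_onsets: list[OnsetEvent],
    angle_onsets: list[OnsetEvent],
    max_gap_s: float | None = None,
) -> float:
    """Mean paired onset difference (angle − E-Skin), seconds.

    Each angle onset is paired with the nearest unused E-Skin onset; the
    pairing must be one-to-one and, when ``max_gap_s`` is given, within
    that window (default: half the median inter-onset interval).  The
    result is positive when the E-Skin channel leads.
    """
    if not eskin_onsets or not angle_onsets:
        raise PairingError("cannot pair empty onset lists")
    if len(eskin_onsets) != len(angle_onsets):
        raise PairingError(
            f"unequal onset counts: {len(eskin_onsets)} E-Skin vs {len(angle_onsets)} angle"
        )
    e_times = np.asarray(sorted(ev.onset_time_s for ev in eskin_onsets))
    a_times = np.asarray(sorted(ev.onset_time_s for ev in angle_onsets))
    if max_gap_s is None:
        gaps = np.diff(a_times)
        max_gap_s = float(np.median(gaps)) / 2.0 if len(gaps) else np.inf
    used = np.zeros(len(e_times), dtype=bool)
    diffs = []
    for at in a_times:
        dist = np.where(used, np.inf, np.abs(e_times - at))
        j = int(np.argmin(dist))
        if not np.isfinite(dist[j]) or dist[j] > max_gap_s:
            raise PairingError(
                f"angle onset at {at:.1f}s has no E-Skin onset within {max_gap_s:.1f}s"
            )
        used[j] = True
        diffs.append(at - e_times[j])
    return float(np.mean(diffs))


@dataclass
class MovementLabel:
    """Rule-based classification of one repetition window."""

    label: str  # a Movement value or "static"
    confidence: str  # "high" | "low"
    evidence: dict[str, float] = field(default_factory=dict)


def _peak_count(values: np.ndarray, peak: float) -> int:
    """Number of distinct response peaks above half the channel maximum."""
    if peak <= 0:
        return 0
    idx, _ = find_peaks(values, height=0.5 * peak, prominence=0.4 * peak, plateau_size=1)
    return len(idx)


def _onset_index(values: np.ndarray, threshold: float) -> float:
    above = np.flatnonzero(np.abs(values) > threshold)
    return float(above[0]) if len(above) else np.inf


def classify_movement(
    channels: dict[Placement, np.ndarray] | dict[Placement, TimeSeries],
    resistance_threshold: float = 6.9,
    dominance_ratio: float = 1.3,
) -> MovementLabel:
    """Classify one repetition from its per-channel resistance-change traces.

    ``channels`` maps placements to the (per-second) resistance-change
    values over the repetition window.  The rule cascade is described in
    the module docstring; conflicting evidence lowers the confidence flag
    but never raises.
    """
    vals = {
        p: np.asarray(v.values if isinstance(v, TimeSeries) else v, dtype=float)
        for p, v in channels.items()
    }
    peaks = {p: float(np.max(np.abs(v))) if len(v) else 0.0 for p, v in vals.items()}
    active = {p for p, pk in peaks.items() if pk > resistance_threshold}
    evidence = {f"peak_{p.value}": pk for p, pk in peaks.items()}
    if not active:
        return MovementLabel(label=STATIC, confidence="high", evidence=evidence)

    def pk(p: Placement) -> float:
        return peaks.get(p, 0.0)

    diag_max = max(pk(Placement.LEFT_DIAGONAL), pk(Placement.RIGHT_DIAGONAL))
    vert_max = max(pk(Placement.TOP_VERTICAL), pk(Placement.BOTTOM_VERTICAL))

    if diag_max > vert_max:
        left = pk(Placement.LEFT_DIAGONAL)
        right = pk(Placement.RIGHT_DIAGONAL)
        lo, hi = min(left, right), max(left, right)
        ratio = np.inf if lo == 0 else hi / lo
        evidence["diag_ratio"] = float(ratio)
        if ratio >= dominance_ratio:
            # lateral flexion: the contralateral sensor responds more strongly
            label = "left_lateral_flexion" if right > left else "right_lateral_flexion"
            return MovementLabel(label=label, confidence="high", evidence=evidence)
        # rotation: near-equal magnitudes, contralateral sensor rises first
        on_l = _onset_index(vals.get(Placement.LEFT_DIAGONAL, np.array([])), resistance_threshold)
        on_r = _onset_index(vals.get(Placement.RIGHT_DIAGONAL, np.array([])), resistance_threshold)
        evidence["onset_left"] = on_l
        evidence["onset_right"] = on_r
        if on_r < on_l:
            return MovementLabel(label="left_rotation", confidence="high", evidence=evidence)
        if on_l < on_r:
            return MovementLabel(label="right_rotation", confidence="high", evidence=evidence)
        # tied onsets: fall back to the magnitude asymmetry, flag low confidence
        label = "left_rotation" if right >= left else "right_rotation"
        return MovementLabel(label=label, confidence="low", evidence=evidence)

    top = vals.get(Placement.TOP_VERTICAL, np.array([]))
    bottom = vals.get(Placement.BOTTOM_VERTICAL, np.array([]))
    top_pk, bottom_pk = pk(Placement.TOP_VERTICAL), pk(Placement.BOTTOM_VERTICAL)
    spiky_top = _peak_count(top, top_pk) >= 2
    spiky_bottom = _peak_count(bottom, bottom_pk) >= 2
    evidence["spiky_top"] = float(spiky_top)
    evidence["spiky_bottom"] = float(spiky_bottom)

    if bottom_pk >= dominance_ratio * top_pk and not spiky_bottom:
        return MovementLabel(label="flexion", confidence="high", evidence=evidence)
    if top_pk > bottom_pk and not spiky_top:
        # sustained top response: pelvic tilt; bottom double-spike marks posterior
        if spiky_bottom and bottom_pk > resistance_threshold:
            return MovementLabel(
                label="posterior_pelvic_tilt", confidence="high", evidence=evidence
            )
        if bottom_pk <= resistance_threshold:
            return MovementLabel(
                label="anterior_pelvic_tilt", confidence="high", evidence=evidence
            )
        return MovementLabel(label="anterior_pelvic_tilt", confidence="low", evidence=evidence)
    if spiky_top:
        return MovementLabel(label="extension", confidence="high", evidence=evidence)
    # conflicting vertical evidence: pick the stronger channel's movement, low confidence
    label = "flexion" if bottom_pk >= top_pk else "anterior_pelvic_tilt"
    return MovementLabel(label=label, confidence="low", evidence=evidence)
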