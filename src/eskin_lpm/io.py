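"""CSV/JSON/YAML formats and pipeline configuration.

Streams travel as RFC-4180 CSV with columns ``timestamp_ms,value,channel``
(one file per channel or several channels per file); ground truth as a
repetition table; aligned per-second data as a wide table keyed on the
second label.  Models and reports are JSON.  The pipeline configuration
is a YAML/JSON document with sections ``script``, ``sensor``, ``noise``,
``preprocessing``, ``calibration``, ``detection`` and a global ``seed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError, FormatError, Movement, Placement, TimeSeries
from .detection import DetectionThresholds
from .preprocessing import AlignedPair, KalmanParams
from .sensor import AdcParams, StrainSensorParams
from .synthetic import RepetitionTruth, SyntheticSession

logger = logging.getLogger(__name__)

__all__ = [
    "read_stream_csv",
    "write_stream_csv",
    "write_session",
    "write_truth_csv",
    "read_truth_csv",
    "write_aligned_csv",
    "read_aligned_csv",
    "PipelineConfig",
]

_STREAM_COLUMNS = ("timestamp_ms", "value", "channel")


def read_stream_csv(path: str | Path, unit: str = "ADU") -> dict[str, TimeSeries]:
    """Read a stream CSV into one :class:`TimeSeries` per channel.

    Rows are validated and sorted by timestamp within channel (a warning
    is logged when the file was unsorted); duplicate (channel, timestamp)
    pairs and missing columns raise :class:`FormatError`.  A ``unit``
    column, when present, overrides the ``unit`` argument.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"stream file not found: {path}")
    # round_trip parsing: written floats (repr) read back bit-identical
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {', '.join(missing)}")
    bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
    if len(bad):
        lines = (bad.index + 2).tolist()[:5]  # +2: header + 1-based
        raise FormatError(f"{path.name}: malformed value(s) at line(s) {lines}")
    streams: dict[str, TimeSeries] = {}
    for channel, group in df.groupby("channel", sort=False):
        ts = group["timestamp_ms"].to_numpy(dtype=float)
        if np.any(np.diff(ts) < 0):
            logger.warning("%s: channel %r rows unsorted; sorting", path.name, channel)
            group = group.sort_values("timestamp_ms", kind="stable")
            ts = group["timestamp_ms"].to_numpy(dtype=float)
        if len(np.unique(ts)) != len(ts):
            raise FormatError(f"{path.name}: duplicate timestamps on channel {channel!r}")
        ch_unit = str(group["unit"].iloc[0]) if "unit" in group.columns else unit
        streams[str(channel)] = TimeSeries(
            ts, group["value"].to_numpy(dtype=float), unit=ch_unit, channel=str(channel)
        )
    return streams


def write_stream_csv(path: str | Path, streams: dict[str, TimeSeries]) -> None:
    frames = [
        pd.DataFrame(
            {
                "timestamp_ms": s.timestamps_ms,
                "value": s.values,
                "channel": name,
                "unit": s.unit,
            }
        )
        for name, s in streams.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_session(session: SyntheticSession, out_dir: str | Path) -> None:
    """Write one CSV per channel plus the ground-truth repetition table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for placement, stream in session.eskin_streams.items():
        write_stream_csv(out / f"eskin_{placement.value}.csv", {placement.value: stream})
    write_stream_csv(out / "angle.csv", {"angle": session.angle_stream})
    write_truth_csv(out / "truth.csv", session.truth)


def write_truth_csv(path: str | Path, truth: list[RepetitionTruth]) -> None:
    pd.DataFrame(
        {
            "rep_id": [r.rep_id for r in truth],
            "movement": [r.movement.value for r in truth],
            "start_ms": [r.start_ms for r in truth],
            "end_ms": [r.end_ms for r in truth],
            "skin_onset_ms": [r.skin_onset_ms for r in truth],
            "angle_onset_ms": [r.angle_onset_ms for r in truth],
            "peak_deg": [r.peak_deg for r in truth],
        }
    ).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> list[RepetitionTruth]:
    df = pd.read_csv(path)
    required = {"rep_id", "movement", "start_ms", "end_ms", "skin_onset_ms",
                "angle_onset_ms", "peak_deg"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"truth file missing column(s) {sorted(missing)}")
    return [
        RepetitionTruth(
            rep_id=int(row.rep_id),
            movement=Movement(row.movement),
            start_ms=float(row.start_ms),
            end_ms=float(row.end_ms),
            skin_onset_ms=float(row.skin_onset_ms),
            angle_onset_ms=float(row.angle_onset_ms),
            peak_deg=float(row.peak_deg),
        )
        for row in df.itertuples()
    ]


def write_aligned_csv(path: str | Path, aligned: AlignedPair) -> None:
    data = {"second": aligned.seconds, "angle": aligned.angle_values}
    for name, values in aligned.eskin_values.items():
        data[name] = values
    pd.DataFrame(data).to_csv(path, index=False)


def read_aligned_csv(path: str | Path) -> AlignedPair:
    df = pd.read_csv(path)
    if "second" not in df.columns or "angle" not in df.columns:
        raise FormatError("aligned file needs 'second' and 'angle' columns")
    eskin = {
        c: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c not in ("second", "angle")
    }
    return AlignedPair(
        seconds=df["second"].to_numpy(dtype=np.int64),
        eskin_values=eskin,
        angle_values=df["angle"].to_numpy(dtype=float),
    )


@dataclass
class PipelineConfig:
    """Validated end-to-end pipeline configuration.

    All randomness flows from ``seed``.  ``movements`` defaults to all
    eight variants; repetitions default to 5 per set × 3 sets.
    """

    seed: int = 0
    movements: list[Movement] = field(default_factory=lambda: list(Movement))
    reps_per_set: int = 5
    n_sets: int = 3
    sensor: StrainSensorParams | None = None  # None -> session default (R0=1400)
    adc: AdcParams = field(default_factory=AdcParams)
    eskin_rate_hz: float = 15.0
    angle_rate_range: tuple[float, float] = (19.0, 19.8)
    angle_rate_hz: float | None = None  # fixed rate overriding the drawn range
    noise_sd_adu: float = 2.0
    angle_noise_sd_deg: float = 0.3
    onset_lead_s: float = 1.0
    rest_resistance: float = 330.0
    quantize: bool = True
    kalman: KalmanParams = field(default_factory=KalmanParams)
    smooth: bool = True
    baseline_window_s: float = 5.0
    n_train: int = 10
    n_test: int = 5
    thresholds: DetectionThresholds | None = field(default_factory=DetectionThresholds)
    refractory_s: float = 3.0
    out_dir: str = "eskin_lpm_out"

    def validate(self) -> None:
        if self.thresholds is None:
            raise ConfigurationError("detection thresholds are required")
        if self.reps_per_set * self.n_sets < self.n_train + self.n_test:
            raise ConfigurationError(
                f"{self.reps_per_set * self.n_sets} repetitions cannot support a "
                f"{self.n_train}/{self.n_test} train/test split"
            )
        if not self.movements:
            raise ConfigurationError("at least one movement must be configured")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        script = raw.get("script", {})
        sensor_sec = raw.get("sensor")
        noise = raw.get("noise", {})
        pre = raw.get("preprocessing", {})
        cal = raw.get("calibration", {})
        det = raw.get("detection", {})
        kalman_sec = pre.get("kalman", {})
        th = det.get("thresholds", {})
        if th is None:
            thresholds = None  # explicit null -> rejected by validate()
        else:
            thresholds = DetectionThresholds(
                angle_deg=float(th.get("angle_deg", 3.0)),
                resistance_ohm=float(th.get("resistance_ohm", 6.9)),
            )
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            movements=[Movement(m) for m in script.get("movements", [m.value for m in Movement])],
            reps_per_set=int(script.get("reps_per_set", 5)),
            n_sets=int(script.get("n_sets", 3)),
            sensor=StrainSensorParams(**sensor_sec) if sensor_sec else None,
            eskin_rate_hz=float(noise.get("eskin_rate_hz", 15.0)),
            angle_rate_hz=(
                float(noise["angle_rate_hz"]) if noise.get("angle_rate_hz") else None
            ),
            noise_sd_adu=float(noise.get("noise_sd_adu", 2.0)),
            angle_noise_sd_deg=float(noise.get("angle_noise_sd_deg", 0.3)),
            onset_lead_s=float(noise.get("onset_lead_s", 1.0)),
            rest_resistance=float(noise.get("rest_resistance", 330.0)),
            quantize=bool(noise.get("quantize", True)),
            kalman=KalmanParams(
                r=float(kalman_sec.get("r", 4.0)),
                p=float(kalman_sec.get("p", 4.0)),
                q=float(kalman_sec.get("q", 0.05)),
            ),
            smooth=bool(pre.get("smooth", True)),
            baseline_window_s=float(pre.get("baseline_window_s", 5.0)),
            n_train=int(cal.get("n_train", 10)),
            n_test=int(cal.get("n_test", 5)),
            thresholds=thresholds,
            refractory_s=float(det.get("refractory_s", 3.0)),
            out_dir=str(raw.get("out_dir", "eskin_lpm_out")),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
        return cls.from_dict(raw)


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
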