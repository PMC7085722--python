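"""Shared carriers and vocabulary for the lumbar-pelvic movement pipeline.

Every stage exchanges :class:`TimeSeries` objects: timestamped scalar
samples with a unit and a channel label.  Timestamps are milliseconds from
a shared session origin so that streams sampled at different rates (the
E-Skin channels near 15 Hz, the reference angle channel near 19-20 Hz)
can be binned onto a common per-second grid later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Movement",
    "Placement",
    "STATIC",
    "TimeSeries",
    "PipelineError",
    "ParameterError",
    "ConfigurationError",
    "RangeError",
    "InsufficientDataError",
    "AlignmentError",
    "DegenerateFitError",
    "CollinearityError",
    "SplitError",
    "PairingError",
    "FormatError",
    "GenerationError",
]


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(PipelineError, ValueError):
    """A numeric parameter violates its documented constraint."""


class ConfigurationError(PipelineError, ValueError):
    """A configuration object is incomplete or inconsistent."""


class RangeError(PipelineError, ValueError):
    """An input value lies outside the physically valid range."""


class InsufficientDataError(PipelineError, ValueError):
    """Not enough samples to carry out the requested computation."""


class AlignmentError(PipelineError, ValueError):
    """Streams share no common time bins."""


class DegenerateFitError(PipelineError, ValueError):
    """The predictor has zero variance; a line cannot be fitted."""


class CollinearityError(PipelineError, ValueError):
    """The multi-predictor design matrix is rank deficient."""


class SplitError(PipelineError, ValueError):
    """Too few repetitions for the requested train/test split."""


class PairingError(PipelineError, ValueError):
    """Onset events from two channels could not be paired one-to-one."""


class FormatError(PipelineError, ValueError):
    """A stream file violates the expected CSV layout."""


class GenerationError(PipelineError, ValueError):
    """The synthetic-session configuration is internally inconsistent."""


class Movement(str, Enum):
    """The five standard lumbar-pelvic movements, split by side/direction."""

    FLEXION = "flexion"
    EXTENSION = "extension"
    ANTERIOR_PELVIC_TILT = "anterior_pelvic_tilt"
    POSTERIOR_PELVIC_TILT = "posterior_pelvic_tilt"
    LEFT_LATERAL_FLEXION = "left_lateral_flexion"
    RIGHT_LATERAL_FLEXION = "right_lateral_flexion"
    LEFT_ROTATION = "left_rotation"
    RIGHT_ROTATION = "right_rotation"


#: Label used by the classifier when no channel shows any movement.
STATIC = "static"


class Placement(str, Enum):
    """E-Skin sensor positions on the back.

    The two vertical sensors sit on the spine (top around T3-T7, bottom
    around L1-L5) and respond to sagittal-plane movements; the two diagonal
    sensors sit towards the left/right scapula and respond to coronal- and
    transverse-plane movements.
    """

    TOP_VERTICAL = "top_vertical"
    BOTTOM_VERTICAL = "bottom_vertical"
    LEFT_DIAGONAL = "left_diagonal"
    RIGHT_DIAGONAL = "right_diagonal"


VALID_UNITS = ("ADU", "ohm", "degree", "strain")


@dataclass
class TimeSeries:
    """Timestamped scalar samples with a unit and channel label.

    Parameters
    ----------
    timestamps_ms:
        Milliseconds from the session origin, monotone non-decreasing.
    values:
        Sample values, same length as ``timestamps_ms``.
    unit:
        One of ``"ADU"``, ``"ohm"``, ``"degree"``, ``"strain"``.
    channel:
        Free-form channel label (e.g. ``"bottom_vertical"`` or ``"angle"``).
    """

    timestamps_ms: np.ndarray
    values: np.ndarray
    unit: str
    channel: str = ""

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps_ms.ndim != 1 or self.values.ndim != 1:
            raise ParameterError("timestamps and values must be 1-D")
        if len(self.timestamps_ms) != len(self.values):
            raise ParameterError(
                f"length mismatch: {len(self.timestamps_ms)} timestamps vs "
                f"{len(self.values)} values on channel {self.channel!r}"
            )
        if self.unit not in VALID_UNITS:
            raise ParameterError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if len(self.timestamps_ms) > 1 and np.any(np.diff(self.timestamps_ms) < 0):
            raise ParameterError(f"timestamps not sorted on channel {self.channel!r}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration_s(self) -> float:
        """Span of the series in seconds (0 for fewer than two samples)."""
        if len(self) < 2:
            return 0.0
        return float(self.timestamps_ms[-1] - self.timestamps_ms[0]) / 1000.0

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "TimeSeries":
        """Copy of this series with new values (and optionally a new unit)."""
        return TimeSeries(
            timestamps_ms=self.timestamps_ms.copy(),
            values=np.asarray(values, dtype=float),
            unit=self.unit if unit is None else unit,
            channel=self.channel,
        )

    def equals(self, other: "TimeSeries") -> bool:
        """Exact equality of timestamps, values, unit and channel."""
        return (
            self.unit == other.unit
            and self.channel == other.channel
            and np.array_equal(self.timestamps_ms, other.timestamps_ms)
            and np.array_equal(self.values, other.values)
        )
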