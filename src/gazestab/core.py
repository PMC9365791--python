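"""Shared domain containers and the package's exception hierarchy.

Conventions used throughout the package
---------------------------------------
Angles are in degrees; time in seconds; accelerations in units of g.
Positive rotation is toward the animal's dorsum for roll and pitch and
toward its left for yaw.  Image-convention vertical axes (y increasing
downward) are inverted at calibration time, never later.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "Plane",
    "FrameOfReference",
    "Modality",
    "AngularTrace",
    "AccelTrace",
    "StimulusProtocol",
    "Phase",
    "PhaseSegmentation",
    "GazestabError",
    "InvalidParameterError",
    "InfeasibleConstructionError",
    "FormatError",
    "QualityError",
    "AlignmentError",
    "InsufficientDataError",
    "UndefinedResultError",
    "FitFailureError",
    "CANONICAL_PROTOCOLS",
]


class GazestabError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(GazestabError, ValueError):
    """A parameter is outside its documented domain."""


class InfeasibleConstructionError(GazestabError, ValueError):
    """Requested ground truth cannot be realized by the generative model."""


class FormatError(GazestabError, ValueError):
    """An input file does not follow the expected dialect."""


class QualityError(GazestabError, ValueError):
    """Input data fail a quality gate (e.g. too many masked frames)."""


class AlignmentError(GazestabError, ValueError):
    """Two series that must share a time base do not."""


class InsufficientDataError(GazestabError, ValueError):
    """Too few samples/values to compute the requested quantity."""


class UndefinedResultError(GazestabError, ValueError):
    """The requested quantity is mathematically undefined on this input."""


class FitFailureError(GazestabError, RuntimeError):
    """A model fit did not converge to a physically meaningful solution."""


class Plane(str, Enum):
    ROLL = "roll"
    PITCH = "pitch"
    YAW = "yaw"


class FrameOfReference(str, Enum):
    EYE_IN_HEAD = "eye_in_head"
    HEAD_IN_SPACE = "head_in_space"


class Modality(str, Enum):
    VIS = "VIS"
    VES = "VES"
    VISVES = "VISVES"


@dataclass
class AngularTrace:
    """Uniformly sampled angle-versus-time series for one rotation plane.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, uniformly spaced (checked to 1e-6 s).
    angle_deg : ndarray
        Angular position in degrees, same length as ``t``.
    plane : Plane
        Rotation plane (roll, pitch or yaw).
    frame : FrameOfReference
        Whether the angle is eye-in-head or head-in-space.
    """

    t: np.ndarray
    angle_deg: np.ndarray
    plane: Plane = Plane.ROLL
    frame: FrameOfReference = FrameOfReference.EYE_IN_HEAD

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        self.plane = Plane(self.plane)
        self.frame = FrameOfReference(self.frame)
        if self.t.ndim != 1 or self.t.shape != self.angle_deg.shape:
            raise InvalidParameterError("t and angle_deg must be 1-D and equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - dt[0]) > 1e-6):
                raise InvalidParameterError("AngularTrace requires uniform sampling")
        if not np.all(np.isfinite(self.angle_deg)):
            raise InvalidParameterError("AngularTrace angles must be finite")

    @property
    def sample_rate(self) -> float:
        if self.t.size < 2:
            raise InvalidParameterError("sample rate undefined for <2 samples")
        return 1.0 / (self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def copy(self, angle_deg: np.ndarray | None = None) -> "AngularTrace":
        return AngularTrace(
            self.t.copy(),
            self.angle_deg.copy() if angle_deg is None else np.asarray(angle_deg, float),
            self.plane,
            self.frame,
        )


@dataclass
class AccelTrace:
    """Three-axis accelerometer series in units of g (ADXL-style sensor)."""

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if not (self.t.shape == self.ax.shape == self.ay.shape == self.az.shape):
            raise InvalidParameterError("accelerometer channels must share one time base")

    @property
    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.ax**2 + self.ay**2 + self.az**2)


#: The four vestibular/visual stimulation conditions: (amplitude deg, speed deg/s).
CANONICAL_PROTOCOLS: tuple[tuple[float, float], ...] = (
    (5.8, 48.7),
    (5.8, 112.94),
    (22.7, 48.7),
    (22.7, 112.94),
)


@dataclass
class StimulusProtocol:
    """One stimulation condition: modality, plane, platform amplitude and speed."""

    modality: Modality = Modality.VES
    plane: Plane = Plane.ROLL
    amplitude_deg: float = 22.7
    speed_deg_s: float = 48.7
    static_hold_s: float = 1.0

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.plane = Plane(self.plane)
        if self.amplitude_deg < 0:
            raise InvalidParameterError("amplitude_deg must be >= 0")
        if self.speed_deg_s <= 0:
            raise InvalidParameterError("speed_deg_s must be > 0")
        if self.static_hold_s < 0:
            raise InvalidParameterError("static_hold_s must be >= 0")


@dataclass
class Phase:
    """One labeled nystagmus interval."""

    kind: str  # "slow" | "quick"
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.kind not in ("slow", "quick"):
            raise InvalidParameterError("phase kind must be 'slow' or 'quick'")
        if not self.end_s > self.start_s:
            raise InvalidParameterError("phase must have positive duration")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PhaseSegmentation:
    """Ordered, non-overlapping slow/quick intervals tiling an eye trace."""

    phases: list[Phase] = field(default_factory=list)
    direction_of_head: int = 1

    def __post_init__(self) -> None:
        if self.direction_of_head not in (-1, 1):
            raise InvalidParameterError("direction_of_head must be +1 or -1")
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise InvalidParameterError("phases must be ordered and non-overlapping")

    def of_kind(self, kind: str) -> list[Phase]:
        return [p for p in self.phases if p.kind == kind]

    @property
    def n_quick(self) -> int:
        return len(self.of_kind("quick"))

    def slow_mask(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask of samples lying inside slow phases."""
        mask = np.zeros(t.shape, dtype=bool)
        for p in self.of_kind("slow"):
            mask |= (t >= p.start_s - 1e-12) & (t <= p.end_s + 1e-12)
        return mask

    @staticmethod
    def all_slow(trace: AngularTrace, direction_of_head: int = 1) -> "PhaseSegmentation":
        """A trivial segmentation labeling the whole trace as one slow phase."""
        return PhaseSegmentation(
            [Phase("slow", float(trace.t[0]), float(trace.t[-1]))], direction_of_head
        )
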