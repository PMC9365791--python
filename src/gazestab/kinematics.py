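"""From tracker tables and accelerometer traces to calibrated angular positions.

The processing chain for video-tracked eyes is:

1. :func:`eye_trajectory` - average the eye labels per frame (masking and
   interpolating low-likelihood frames),
2. :func:`subtract_body_motion` - remove the shared body/breathing component
   using the body labels,
3. :func:`pixels_to_degrees` - convert pixel displacement into ocular rotation
   using the measured eye diameter (chord model by default),

and for head motion either :func:`accel_to_orientation` (roll/pitch from the
gravity component of a 3-axis accelerometer) or the platform command profile
(yaw, which gravity cannot observe).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .core import (
    AccelTrace,
    AlignmentError,
    AngularTrace,
    FrameOfReference,
    InvalidParameterError,
    Plane,
    QualityError,
    UndefinedResultError,
)

__all__ = [
    "Calibration",
    "TrackerTable",
    "read_tracker_table",
    "write_tracker_table",
    "eye_trajectory",
    "subtract_body_motion",
    "pixels_to_degrees",
    "trajectory_to_trace",
    "accel_to_orientation",
    "estimate_velocity",
    "align_traces",
]


@dataclass
class Calibration:
    """Pixel-to-angle conversion parameters.

    ``eye_diameter_mm`` is the measured diameter of the eye along the motion
    axis; ``mm_per_px`` comes from comparing that diameter to its extent in
    the video.  ``y_axis_down`` records the image convention so that vertical
    displacements can be sign-corrected once, here, and nowhere else.
    """

    eye_diameter_mm: float = 1.5
    mm_per_px: float = 0.01
    frame_rate: float = 100.0
    y_axis_down: bool = True
    angle_mode: str = "chord"  # "chord" | "arc"

    def __post_init__(self) -> None:
        if self.eye_diameter_mm <= 0 or self.mm_per_px <= 0 or self.frame_rate <= 0:
            raise InvalidParameterError("calibration values must be positive")
        if self.angle_mode not in ("chord", "arc"):
            raise InvalidParameterError("angle_mode must be 'chord' or 'arc'")


@dataclass
class TrackerTable:
    """Parsed pose-tracker output: per-label x/y/likelihood per frame.

    ``data`` has a 2-level column MultiIndex (bodypart, coord) with coords
    x, y, likelihood; the index is the frame number.
    """

    data: pd.DataFrame
    eye_labels: list[str]
    body_labels: list[str]
    scorer: str = "gazestab"

    def __post_init__(self) -> None:
        idx = self.data.index.to_numpy()
        if len(idx) > 1 and np.any(np.diff(idx) <= 0):
            raise InvalidParameterError("frame indices must be strictly increasing")
        if not self.eye_labels:
            raise InvalidParameterError("at least one eye label is required")
        lik = self.data.loc[:, (slice(None), "likelihood")].to_numpy()
        if np.any((lik < 0) | (lik > 1)):
            raise InvalidParameterError("likelihoods must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def xy(self, label: str) -> np.ndarray:
        """(n_frames, 2) array of a label's pixel coordinates."""
        return self.data[label][["x", "y"]].to_numpy()

    def likelihood(self, label: str) -> np.ndarray:
        return self.data[(label, "likelihood")].to_numpy()


def _is_body_label(name: str) -> bool:
    return name.lower().startswith("body")


def read_tracker_table(path, eye_labels=None, body_labels=None) -> TrackerTable:
    """Read a pose-tracker CSV with the three header rows scorer/bodyparts/coords.

    Labels are split into eye and body rosters either explicitly or, by
    default, by the ``body*`` name prefix.  Raises :class:`FormatError` for a
    file that does not follow the dialect and a row-level error naming the
    frame for non-numeric cells.
    """
    from .io import read_tracker_csv

    return read_tracker_csv(path, eye_labels=eye_labels, body_labels=body_labels)


def write_tracker_table(table: TrackerTable, path) -> None:
    from .io import write_tracker_csv

    write_tracker_csv(table, path)


def eye_trajectory(
    table: TrackerTable,
    min_likelihood: float = 0.8,
    max_masked_fraction: float = 0.5,
    max_gap_s: float = 0.2,
    frame_rate: float = 100.0,
) -> tuple[np.ndarray, float]:
    """Per-frame mean of the eye-label coordinates, likelihood-gated.

    Frames in which *any* eye label falls below ``min_likelihood`` are masked
    and linearly interpolated from their neighbors; masked gaps longer than
    ``max_gap_s`` are left as NaN and warned about instead (quick phases last
    tens of milliseconds, so bridging long gaps would fabricate dynamics).
    Returns ``(xy, masked)`` where ``xy`` is (n_frames, 2) in pixels and
    ``masked`` the masked fraction.  More than ``max_masked_fraction`` masked
    frames raises :class:`QualityError`.
    """
    coords = np.stack([table.xy(lbl) for lbl in table.eye_labels])  # (L, n, 2)
    lik = np.stack([table.likelihood(lbl) for lbl in table.eye_labels])  # (L, n)
    mean_xy = coords.mean(axis=0)
    bad = np.any(lik < min_likelihood, axis=0)
    frac = float(bad.mean())
    if frac > max_masked_fraction:
        raise QualityError(
            f"{frac:.0%} of frames below likelihood {min_likelihood}; "
            f"limit is {max_masked_fraction:.0%}"
        )
    if bad.any():
        good = ~bad
        if good.sum() < 2:
            raise QualityError("fewer than 2 usable frames for interpolation")
        idx = np.arange(len(bad))
        for k in range(2):
            mean_xy[bad, k] = np.interp(idx[bad], idx[good], mean_xy[good, k])
        max_gap_frames = int(np.floor(max_gap_s * frame_rate))
        long_gaps = [
            (a, b) for a, b in _bool_runs(bad) if (b - a) > max_gap_frames
        ]
        if long_gaps:
            for a, b in long_gaps:
                mean_xy[a:b] = np.nan
            warnings.warn(
                f"{len(long_gaps)} masked gap(s) longer than {max_gap_s} s left "
                "as NaN (not interpolated)",
                stacklevel=2,
            )
    return mean_xy, frac


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[splits + 1]))
    stops = np.concatenate((idx[splits] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def subtract_body_motion(eye_px: np.ndarray, body_px: np.ndarray) -> np.ndarray:
    """Remove the shared body/breathing component from an eye trajectory.

    ``corrected = eye - (body - mean(body))`` per axis, so a motion component
    common to eye and body labels (breathing, residual platform vibration)
    cancels exactly while the eye's own excursion is preserved.
    """
    eye_px = np.asarray(eye_px, float)
    body_px = np.asarray(body_px, float)
    if eye_px.shape != body_px.shape:
        raise AlignmentError(
            f"eye ({eye_px.shape}) and body ({body_px.shape}) trajectories differ in shape"
        )
    return eye_px - (body_px - body_px.mean(axis=0, keepdims=True))


def pixels_to_degrees(
    displacement_px: np.ndarray | float, cal: Calibration, axis: str = "x"
) -> np.ndarray | float:
    """Convert a pixel displacement of the pupil into an ocular rotation angle.

    The default chord model treats the on-image displacement d (mm) as the
    chord of the rotation on an eye of diameter D:  theta = 2 asin(d / D).
    The small-angle arc model theta = (2 d / D) (180/pi) is available via
    ``cal.angle_mode == "arc"``.  Vertical displacements are sign-inverted
    when ``cal.y_axis_down`` so that positive angles follow the package's
    dorsum-/left-positive convention.
    """
    d = np.asarray(displacement_px, dtype=float)
    scalar = d.ndim == 0
    d_mm = d * cal.mm_per_px
    D = cal.eye_diameter_mm
    if np.any(np.abs(d_mm) > D):
        raise InvalidParameterError(
            "pixel displacement exceeds the eye diameter; check calibration"
        )
    if cal.angle_mode == "chord":
        theta = np.degrees(2.0 * np.arcsin(d_mm / D))
    else:
        theta = np.degrees(2.0 * d_mm / D)
    if axis == "y" and cal.y_axis_down:
        theta = -theta
    return float(theta) if scalar else theta


def trajectory_to_trace(
    traj_px: np.ndarray,
    cal: Calibration,
    plane: Plane = Plane.ROLL,
    axis: str = "x",
    reference: str = "first",
) -> AngularTrace:
    """Full pixel trajectory -> :class:`AngularTrace` (eye-in-head).

    Displacement is taken along ``axis`` relative to the first frame
    (``reference="first"``) or the trajectory median (``"median"``).
    """
    traj_px = np.asarray(traj_px, float)
    col = {"x": 0, "y": 1}[axis]
    series = traj_px[:, col]
    ref = series[0] if reference == "first" else np.median(series)
    angles = pixels_to_degrees(series - ref, cal, axis=axis)
    t = np.arange(len(series)) / cal.frame_rate
    return AngularTrace(t, angles, plane, FrameOfReference.EYE_IN_HEAD)


def accel_to_orientation(
    accel: AccelTrace, smoothing_window: int = 5
) -> dict[str, AngularTrace]:
    """Roll and pitch head orientation from the gravity component.

    Assumes quasi-static tilts (the gravity vector dominates): after a
    moving-average smooth, ``roll = atan2(ay, -az)`` and
    ``pitch = atan2(-ax, sqrt(ay^2 + az^2))``, both in degrees.  Yaw is not
    produced - rotation about the gravity axis is unobservable from a static
    accelerometer and must come from the platform command profile.

    A warning is issued when |a| deviates from 1 g by more than 20% on more
    than 10% of samples (dynamic acceleration violating the assumption).
    """
    mag = accel.magnitude
    if np.all(mag == 0):
        raise UndefinedResultError("all-zero accelerometer signal: orientation undefined")
    if np.mean(np.abs(mag - 1.0) > 0.2) > 0.1:
        warnings.warn(
            "accelerometer magnitude far from 1 g on >10% of samples; "
            "quasi-static assumption questionable",
            stacklevel=2,
        )
    if smoothing_window < 1:
        raise InvalidParameterError("smoothing_window must be >= 1")

    def smooth(x: np.ndarray) -> np.ndarray:
        if smoothing_window == 1 or len(x) < smoothing_window:
            return x
        kernel = np.ones(smoothing_window) / smoothing_window
        pad = smoothing_window // 2
        xp = np.pad(x, pad, mode="edge")
        out = np.convolve(xp, kernel, mode="same")[pad : pad + len(x)]
        return out

    ax, ay, az = smooth(accel.ax), smooth(accel.ay), smooth(accel.az)
    roll = np.degrees(np.arctan2(ay, -az))
    pitch = np.degrees(np.arctan2(-ax, np.sqrt(ay**2 + az**2)))
    return {
        "roll": AngularTrace(accel.t, roll, Plane.ROLL, FrameOfReference.HEAD_IN_SPACE),
        "pitch": AngularTrace(accel.t, pitch, Plane.PITCH, FrameOfReference.HEAD_IN_SPACE),
    }


def estimate_velocity(
    trace: AngularTrace, window: int = 7, polyorder: int = 2
) -> np.ndarray:
    """Angular velocity (deg/s) by local-polynomial (Savitzky-Golay) differentiation.

    Endpoints are handled by the filter's one-sided polynomial fits
    (``mode="interp"``), so the output has the input's length.
    """
    if window % 2 == 0 or window <= polyorder:
        raise InvalidParameterError("window must be odd and > polyorder")
    if window >= trace.t.size:
        raise InvalidParameterError("window must be shorter than the trace")
    dt = trace.t[1] - trace.t[0]
    return savgol_filter(
        trace.angle_deg, window, polyorder, deriv=1, delta=dt, mode="interp"
    )


def align_traces(
    eye: AngularTrace, head: AngularTrace, max_lag_s: float = 0.3
) -> tuple[float, AngularTrace, AngularTrace]:
    """Estimate the eye-after-head latency and return the lag-compensated pair.

    Both traces are resampled onto the finer time base over their common
    support, velocities are computed, and the lag maximizing the normalized
    cross-correlation of |velocity| over +/- ``max_lag_s`` is returned
    (positive = eye lags head).  The eye trace is then advanced by that lag
    and both are trimmed to common support.
    """
    t0 = max(eye.t[0], head.t[0])
    t1 = min(eye.t[-1], head.t[-1])
    if t1 <= t0:
        raise AlignmentError("traces have no overlapping time support")
    dt = min(eye.t[1] - eye.t[0], head.t[1] - head.t[0])
    t = np.arange(t0, t1 + dt / 2, dt)
    e = np.interp(t, eye.t, eye.angle_deg)
    h = np.interp(t, head.t, head.angle_deg)
    ve = np.abs(np.gradient(e, dt))
    vh = np.abs(np.gradient(h, dt))
    if np.std(ve) == 0 or np.std(vh) == 0:
        raise UndefinedResultError("constant trace: lag undefined")
    ve = ve - ve.mean()
    vh = vh - vh.mean()
    max_shift = int(round(max_lag_s / dt))
    best_lag, best_r = 0, -np.inf
    for s in range(-max_shift, max_shift + 1):
        if s >= 0:
            a, b = ve[s:], vh[: len(vh) - s]
        else:
            a, b = ve[: len(ve) + s], vh[-s:]
        if len(a) < 10:
            continue
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        if denom == 0:
            continue
        r = float(np.dot(a, b) / denom)
        if r > best_r:
            best_r, best_lag = r, s
    lag_s = best_lag * dt
    e_shifted = np.interp(t + lag_s, t, e, left=e[0], right=e[-1])
    eye_aligned = AngularTrace(t, e_shifted, eye.plane, eye.frame)
    head_resampled = AngularTrace(t, h, head.plane, head.frame)
    return lag_s, eye_aligned, head_resampled
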