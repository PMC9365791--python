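"""Nystagmus phase segmentation and the two VOR gain estimators.

Two gains are computed, matching how compensatory eye movements are
quantified in gaze-stabilization experiments:

* **position gain** - ratio of the areas under the curve (AUC) of |eye| and
  |head| angular position over the active-movement window, computed on the
  desaccaded (quick-phase-removed) eye trace;
* **dynamic gain** - ratio of eye to head angular velocity during the slow
  phase, here the median sample-wise ratio restricted to samples with
  appreciable head velocity (with an optional explicit two-timestamp mode).

Quick phases are the ballistic resetting movements of nystagmus: they move
in the *same* direction as the head and much faster than the compensatory
slow phase, which is what :func:`segment_phases` exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    AngularTrace,
    InsufficientDataError,
    InvalidParameterError,
    Phase,
    PhaseSegmentation,
    UndefinedResultError,
)
from .kinematics import align_traces, estimate_velocity

__all__ = [
    "PhaseStats",
    "GainEstimate",
    "segment_phases",
    "phase_stats",
    "desaccade",
    "position_gain",
    "dynamic_gain",
    "active_window",
]


@dataclass
class PhaseStats:
    """Per-event durations, amplitudes and mean velocities for each phase kind."""

    quick_durations_s: np.ndarray
    quick_amplitudes_deg: np.ndarray
    quick_velocities_deg_s: np.ndarray
    slow_durations_s: np.ndarray
    slow_amplitudes_deg: np.ndarray
    slow_velocities_deg_s: np.ndarray

    def summary(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for kind in ("quick", "slow"):
            for what in ("durations_s", "amplitudes_deg", "velocities_deg_s"):
                arr = getattr(self, f"{kind}_{what}")
                out[f"{kind}_mean_{what}"] = float(np.mean(arr)) if arr.size else float("nan")
                out[f"{kind}_sd_{what}"] = (
                    float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
                )
        out["n_quick"] = int(self.quick_durations_s.size)
        out["n_slow"] = int(self.slow_durations_s.size)
        return out


@dataclass
class GainEstimate:
    """A gain with the analysis window and sample count it was computed under."""

    gain: float
    kind: str  # "position" | "dynamic"
    window: tuple[float, float]
    n_valid_samples: int

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise InvalidParameterError("gain must be >= 0")
        if self.n_valid_samples <= 0:
            raise InvalidParameterError("n_valid_samples must be > 0")


def _interval_velocities(trace: AngularTrace) -> np.ndarray:
    """Per-interval (first-difference) velocities in deg/s, length n-1.

    Quick phases last only a few samples at video frame rates; first
    differences keep their boundaries crisp where a wider local-polynomial
    differentiator would smear them below threshold.
    """
    dt = trace.t[1] - trace.t[0]
    return np.diff(trace.angle_deg) / dt


def segment_phases(
    eye: AngularTrace,
    head_direction: int,
    speed_factor: float = 3.0,
    min_quick_s: float = 0.008,
    merge_gap_s: float = 0.005,
) -> PhaseSegmentation:
    """Label each part of an eye trace as slow (compensatory) or quick (resetting).

    A sample interval is a quick-phase candidate when its velocity has the
    same sign as ``head_direction`` *and* its speed exceeds ``speed_factor``
    times the median speed of slow-direction intervals.  Candidate runs
    separated by gaps shorter than ``merge_gap_s`` are merged; events shorter
    than ``min_quick_s`` are discarded.  Everything else is slow phase.
    Deterministic for fixed parameters.
    """
    if head_direction not in (-1, 1):
        raise InvalidParameterError("head_direction must be +1 or -1")
    if eye.t.size < 3:
        raise InsufficientDataError("trace too short to segment")
    v = _interval_velocities(eye)
    dt = eye.t[1] - eye.t[0]

    slow_dir = np.sign(v) == -head_direction
    if not slow_dir.any() or np.all(v == 0):
        warnings.warn("constant or one-sided trace: returning a single slow phase",
                      stacklevel=2)
        return PhaseSegmentation.all_slow(eye, head_direction)
    threshold = speed_factor * float(np.median(np.abs(v[slow_dir])))
    candidate = (np.sign(v) == head_direction) & (np.abs(v) > threshold)

    # merge candidate runs across sub-merge_gap gaps
    gap_samples = int(np.floor(merge_gap_s / dt))
    runs = _runs(candidate)
    merged: list[list[int]] = []
    for start, stop in runs:
        if merged and start - merged[-1][1] <= gap_samples:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    min_samples = max(1, int(np.ceil(min_quick_s / dt - 1e-9)))
    events = [(a, b) for a, b in merged if (b - a) >= min_samples]

    phases: list[Phase] = []
    cursor = float(eye.t[0])
    for a, b in events:
        start, end = float(eye.t[a]), float(eye.t[b])
        if start > cursor + 1e-12:
            phases.append(Phase("slow", cursor, start))
        phases.append(Phase("quick", start, end))
        cursor = end
    if cursor < float(eye.t[-1]) - 1e-12:
        phases.append(Phase("slow", cursor, float(eye.t[-1])))
    if not phases:
        phases = [Phase("slow", float(eye.t[0]), float(eye.t[-1]))]
    return PhaseSegmentation(phases, head_direction)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of an interval mask as (start, stop) sample indices.

    ``stop`` indexes the sample *after* the last True interval, i.e. the run
    covers t[start]..t[stop].
    """
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[splits + 1]))
    stops = np.concatenate((idx[splits] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def phase_stats(seg: PhaseSegmentation, eye: AngularTrace) -> PhaseStats:
    """Per-event duration, amplitude and mean velocity for both phase kinds.

    amplitude = |angle(end) - angle(start)|; velocity = amplitude/duration.
    """
    def per_kind(kind: str):
        dur, amp = [], []
        for p in seg.of_kind(kind):
            a = np.interp(p.start_s, eye.t, eye.angle_deg)
            b = np.interp(p.end_s, eye.t, eye.angle_deg)
            dur.append(p.duration_s)
            amp.append(abs(b - a))
        dur = np.asarray(dur)
        amp = np.asarray(amp)
        vel = amp / dur if dur.size else np.asarray([])
        return dur, amp, vel

    qd, qa, qv = per_kind("quick")
    sd, sa, sv = per_kind("slow")
    return PhaseStats(qd, qa, qv, sd, sa, sv)


def desaccade(eye: AngularTrace, seg: PhaseSegmentation) -> AngularTrace:
    """Remove quick-phase displacements so slow-phase motion integrates cleanly.

    Each quick phase is replaced by a linear bridge that continues the local
    slow-phase velocity (mean slope of the adjacent slow phases), and all
    later samples are shifted so the trace stays continuous.  Bridging with
    the slow trend - rather than holding flat - keeps the reconstructed
    cumulative slow-phase trajectory unbiased even when quick phases occupy
    an appreciable fraction of the rotation.
    """
    x = eye.angle_deg
    t = eye.t
    out = x.copy()
    shift = 0.0
    phases = seg.phases
    for pi, p in enumerate(phases):
        if p.kind != "quick":
            continue
        i0 = int(np.searchsorted(t, p.start_s - 1e-12))
        i1 = min(int(np.searchsorted(t, p.end_s - 1e-12)), len(t) - 1)
        slopes = []
        for q in (phases[pi - 1] if pi > 0 else None,
                  phases[pi + 1] if pi + 1 < len(phases) else None):
            if q is not None and q.kind == "slow" and q.duration_s > 0:
                a = np.interp(q.start_s, t, x)
                b = np.interp(q.end_s, t, x)
                slopes.append((b - a) / q.duration_s)
        v_slow = float(np.mean(slopes)) if slopes else 0.0
        start_val = x[i0] - shift
        out[i0 : i1 + 1] = start_val + v_slow * (t[i0 : i1 + 1] - t[i0])
        shift += (x[i1] - x[i0]) - v_slow * (t[i1] - t[i0])
        out[i1 + 1 :] = x[i1 + 1 :] - shift
    return eye.copy(angle_deg=out)


def active_window(head: AngularTrace, onset_fraction: float = 0.05) -> tuple[float, float]:
    """Interval of the head's active movement (first suprathreshold velocity block).

    Samples with |v_head| above ``onset_fraction`` x peak speed are active;
    sub-50 ms dips below threshold are bridged and the *first* contiguous
    block is returned, so the window covers the dynamic tilt but excludes a
    subsequent static hold and any later return-to-level movement.
    """
    v = estimate_velocity(head)
    peak = float(np.max(np.abs(v)))
    if peak < 1e-9:
        raise UndefinedResultError("motionless head trace: no active window")
    mask = np.abs(v) > onset_fraction * peak
    dt = head.t[1] - head.t[0]
    runs = _runs(mask[:-1])  # interval-compatible view
    if not runs:
        raise UndefinedResultError("no samples above the onset threshold")
    bridged: list[list[int]] = []
    gap = int(round(0.05 / dt))
    for a, b in runs:
        if bridged and a - bridged[-1][1] <= gap:
            bridged[-1][1] = b
        else:
            bridged.append([a, b])
    a, b = bridged[0]
    return float(head.t[a]), float(head.t[b])


def _resample_pair(eye: AngularTrace, head: AngularTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t0 = max(eye.t[0], head.t[0])
    t1 = min(eye.t[-1], head.t[-1])
    dt = min(eye.t[1] - eye.t[0], head.t[1] - head.t[0])
    t = np.arange(t0, t1 + dt / 2, dt)
    return t, np.interp(t, eye.t, eye.angle_deg), np.interp(t, head.t, head.angle_deg)


def position_gain(
    eye: AngularTrace,
    head: AngularTrace,
    seg: PhaseSegmentation | None = None,
    window: tuple[float, float] | None = None,
) -> GainEstimate:
    """AUC-ratio position gain over the active-movement window.

    The eye trace is desaccaded using ``seg`` (quick-phase displacements
    subtracted), both traces are re-zeroed at the window start, and the gain
    is the ratio of trapezoidal integrals of |angle|:
    ``AUC_eye / AUC_head``.  Re-zeroing makes the estimate invariant to
    static offsets in either trace.
    """
    if window is None:
        window = active_window(head)
    if seg is None:
        seg = PhaseSegmentation.all_slow(eye)
    eye_d = desaccade(eye, seg)
    t, e, h = _resample_pair(eye_d, head)
    sel = (t >= window[0]) & (t <= window[1])
    if sel.sum() < 2:
        raise InsufficientDataError("analysis window contains <2 samples")
    tw, ew, hw = t[sel], e[sel], h[sel]
    ew = ew - ew[0]
    hw = hw - hw[0]
    auc_h = float(np.trapezoid(np.abs(hw), tw))
    if auc_h == 0:
        raise UndefinedResultError("head AUC is zero: position gain undefined")
    auc_e = float(np.trapezoid(np.abs(ew), tw))
    return GainEstimate(auc_e / auc_h, "position", window, int(sel.sum()))


def dynamic_gain(
    eye: AngularTrace,
    head: AngularTrace,
    seg: PhaseSegmentation | None = None,
    head_speed_floor: float = 0.2,
    align: bool = True,
    two_points: tuple[float, float] | None = None,
) -> GainEstimate:
    """Slow-phase velocity-ratio gain.

    Default mode: after compensating the oculomotor latency (cross-correlation
    alignment of the velocity traces; disable with ``align=False``), the gain
    is the median of |v_eye| / |v_head| over slow-phase samples with
    |v_head| >= ``head_speed_floor`` x peak head speed.  The median is robust
    to near-zero head-velocity samples; the floor removes the rest.

    ``two_points=(t1, t2)`` instead returns the classical two-point ratio
    |v_eye(t1..t2)| / |v_head(t1..t2)| from the displacement between the two
    timestamps.
    """
    if two_points is not None:
        t1, t2 = two_points
        if not t2 > t1:
            raise InvalidParameterError("two_points must be ordered")
        de = np.interp(t2, eye.t, eye.angle_deg) - np.interp(t1, eye.t, eye.angle_deg)
        dh = np.interp(t2, head.t, head.angle_deg) - np.interp(t1, head.t, head.angle_deg)
        if dh == 0:
            raise UndefinedResultError("zero head displacement between the two points")
        return GainEstimate(abs(de / dh), "dynamic", (t1, t2), 2)

    if align:
        _, eye, head = align_traces(eye, head)
    if seg is None:
        seg = PhaseSegmentation.all_slow(eye)
    t, e, h = _resample_pair(eye, head)
    dt = t[1] - t[0]
    base = AngularTrace(t, h, head.plane, head.frame)
    vh = estimate_velocity(base)
    ve = estimate_velocity(AngularTrace(t, e, eye.plane, eye.frame))
    peak = float(np.max(np.abs(vh)))
    if peak == 0:
        raise UndefinedResultError("motionless head trace: dynamic gain undefined")
    valid = (np.abs(vh) >= head_speed_floor * peak) & seg.slow_mask(t)
    n = int(valid.sum())
    if n < 10:
        raise InsufficientDataError(f"only {n} valid samples (<10) for dynamic gain")
    ratio = np.abs(ve[valid]) / np.abs(vh[valid])
    window = (float(t[valid][0]), float(t[valid][-1]))
    return GainEstimate(float(np.median(ratio)), "dynamic", window, n)
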