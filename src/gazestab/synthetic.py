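"""Synthetic recordings with known ground truth for every pipeline stage.

The generator emulates the four kinds of input the analysis consumes -
pose-tracker label tables, 3-axis accelerometer traces, extraocular-muscle
EMG with stimulus epochs, and intracellular EPSP trains - so that every
estimator can be exercised against stored ground truth without any
recorded data.  Defaults encode the study conditions the package targets:
plane-specific VOR gains (dynamic 0.77/0.60/0.69 and position
0.67/0.45/0.64 for roll/pitch/yaw), quick-phase nystagmus statistics
(0.024 s, 1.72 deg), the four vestibular/visual protocols
(5.8 or 22.7 deg at 48.7 or 112.94 deg/s), 10-pulse 10-Hz EPSP trains,
and a 7-frame eye-after-tail lag.

All stochastic operations take an explicit integer seed; one generator
stream (or a spawned substream) per operation call, so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .core import (
    AccelTrace,
    AngularTrace,
    FrameOfReference,
    InfeasibleConstructionError,
    InvalidParameterError,
    Modality,
    Phase,
    PhaseSegmentation,
    Plane,
    StimulusProtocol,
)
from .emg import EMGTrial
from .gaze import active_window, position_gain
from .kinematics import Calibration, TrackerTable
from .psp import PSPTrain

__all__ = [
    "PLANE_GAIN_DEFAULTS",
    "QUICK_DURATION_S",
    "QUICK_AMPLITUDE_DEG",
    "HeadMotionProfile",
    "GroundTruth",
    "SwimCoupling",
    "make_head_motion",
    "make_vor_eye_trace",
    "insert_nystagmus",
    "make_tracker_table",
    "make_emg_trial",
    "make_psp_train",
    "make_swim_coupling",
    "vor_fixture",
    "nystagmus_fixture",
]

#: (dynamic gain, position gain) defaults per rotation plane
PLANE_GAIN_DEFAULTS: dict[Plane, tuple[float, float]] = {
    Plane.ROLL: (0.77, 0.67),
    Plane.PITCH: (0.60, 0.45),
    Plane.YAW: (0.69, 0.64),
}

#: quick-phase nystagmus defaults (mean duration and amplitude)
QUICK_DURATION_S = 0.024
QUICK_AMPLITUDE_DEG = 1.72

#: mean platform accelerations (deg/s^2) for the low/high speed protocols
MEAN_ACCEL_LOW_DEG_S2 = 305.75
MEAN_ACCEL_HIGH_DEG_S2 = 915.73

#: relative SD and truncation bounds of the quick-phase event jitter
_JITTER_REL_SD = 0.3
_JITTER_BOUNDS = (0.5, 1.5)


@dataclass
class HeadMotionProfile:
    """Head-in-space rotation with its synthesized accelerometer signal."""

    trace: AngularTrace
    accel: AccelTrace
    peak_velocity_deg_s: float
    mean_accel_deg_s2: float
    dynamic_interval: tuple[float, float]


@dataclass
class GroundTruth:
    """Generator-side counterparts of every estimated quantity."""

    position_gain: float = 0.67
    dynamic_gain: float = 0.77
    quick_duration_s: float = QUICK_DURATION_S
    quick_amplitude_deg: float = QUICK_AMPLITUDE_DEG
    latency_s: float | None = None
    spike_times: np.ndarray | None = None
    epsp_amplitudes_mv: np.ndarray | None = None
    decay_tau_s: float | None = None
    eye_tail_lag_frames: int | None = None
    quick_durations_s: np.ndarray | None = None
    quick_amplitudes_deg: np.ndarray | None = None

    def __post_init__(self) -> None:
        for g in (self.position_gain, self.dynamic_gain):
            if not 0.0 < g <= 1.2:
                raise InvalidParameterError("gains must lie in (0, 1.2]")
        if self.quick_duration_s <= 0:
            raise InvalidParameterError("quick_duration_s must be > 0")


@dataclass
class SwimCoupling:
    """Tail and binocular eye position series with the ground-truth lag."""

    tail: np.ndarray
    left_eye: np.ndarray
    right_eye: np.ndarray
    frame_rate: float
    lag_frames: int


def _default_accel(speed_deg_s: float) -> float:
    return MEAN_ACCEL_LOW_DEG_S2 if speed_deg_s <= 80.0 else MEAN_ACCEL_HIGH_DEG_S2


def _tilt_angle(tau: np.ndarray, amplitude: float, a: float, v: float) -> np.ndarray:
    """Closed-form trapezoidal-velocity tilt angle, 0 -> amplitude over [0, T].

    Falls back to a triangular velocity profile when the amplitude is too
    small to reach the commanded speed.  tau is time since tilt onset.
    """
    ramp_dist = v**2 / (2 * a)
    if 2 * ramp_dist >= amplitude:
        v = np.sqrt(a * amplitude)
        t_ramp = v / a
        t_plateau = 0.0
    else:
        t_ramp = v / a
        t_plateau = (amplitude - 2 * ramp_dist) / v
    T = 2 * t_ramp + t_plateau
    th = np.zeros_like(tau)
    m1 = (tau >= 0) & (tau < t_ramp)
    th[m1] = 0.5 * a * tau[m1] ** 2
    m2 = (tau >= t_ramp) & (tau < t_ramp + t_plateau)
    th[m2] = 0.5 * a * t_ramp**2 + v * (tau[m2] - t_ramp)
    m3 = (tau >= t_ramp + t_plateau) & (tau < T)
    th[m3] = amplitude - 0.5 * a * (T - tau[m3]) ** 2
    th[tau >= T] = amplitude
    return th


def tilt_duration(amplitude_deg: float, speed_deg_s: float, accel_deg_s2: float) -> float:
    """Duration of the dynamic tilt for a trapezoidal-velocity profile."""
    ramp_dist = speed_deg_s**2 / (2 * accel_deg_s2)
    if 2 * ramp_dist >= amplitude_deg:
        v = np.sqrt(accel_deg_s2 * amplitude_deg)
        return 2 * v / accel_deg_s2
    return 2 * speed_deg_s / accel_deg_s2 + (amplitude_deg - 2 * ramp_dist) / speed_deg_s


def peak_tilt_velocity(amplitude_deg: float, speed_deg_s: float, accel_deg_s2: float) -> float:
    ramp_dist = speed_deg_s**2 / (2 * accel_deg_s2)
    if 2 * ramp_dist >= amplitude_deg:
        return float(np.sqrt(accel_deg_s2 * amplitude_deg))
    return speed_deg_s


def make_head_motion(
    protocol: StimulusProtocol,
    sample_rate: float = 100.0,
    seed: int = 0,
    accel_deg_s2: float | None = None,
    accel_noise_g: float = 0.01,
    pre_hold_s: float = 0.5,
    post_hold_s: float = 0.5,
    return_to_level: bool = True,
) -> HeadMotionProfile:
    """Trapezoidal-velocity platform tilt with a gravity-frame accelerometer signal.

    The platform accelerates at ``accel_deg_s2`` (defaults: the measured
    305.75 / 915.73 deg/s^2 for the low-/high-speed protocols) to the
    commanded speed, holds it, decelerates to rest exactly at
    ``amplitude_deg``, holds for ``static_hold_s`` and, when
    ``return_to_level``, mirrors the tilt back to level.  The accelerometer
    channels are the rotated gravity vector plus zero-mean noise.
    """
    if sample_rate < 50:
        raise InvalidParameterError("sample_rate must be >= 50 Hz")
    if protocol.speed_deg_s <= 0:
        raise InvalidParameterError("speed must be positive")
    a = _default_accel(protocol.speed_deg_s) if accel_deg_s2 is None else accel_deg_s2
    if a <= 0:
        raise InvalidParameterError("acceleration must be positive")
    amp = protocol.amplitude_deg

    if amp == 0:
        T = 0.0
    else:
        T = tilt_duration(amp, protocol.speed_deg_s, a)
    total = pre_hold_s + T + protocol.static_hold_s + (T if return_to_level else 0.0) + post_hold_s
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate

    angle = np.zeros(n)
    if amp > 0:
        angle += _tilt_angle(t - pre_hold_s, amp, a, protocol.speed_deg_s)
        if return_to_level:
            t_ret = pre_hold_s + T + protocol.static_hold_s
            angle -= _tilt_angle(t - t_ret, amp, a, protocol.speed_deg_s)
    trace = AngularTrace(t, angle, protocol.plane, FrameOfReference.HEAD_IN_SPACE)

    rng = np.random.default_rng(seed)
    th = np.radians(angle)
    if protocol.plane is Plane.ROLL:
        ax, ay, az = np.zeros(n), np.sin(th), -np.cos(th)
    elif protocol.plane is Plane.PITCH:
        ax, ay, az = -np.sin(th), np.zeros(n), -np.cos(th)
    else:  # yaw: gravity is unchanged by rotation about the vertical axis
        ax, ay, az = np.zeros(n), np.zeros(n), -np.ones(n)
    noise = rng.normal(0.0, accel_noise_g, size=(3, n)) if accel_noise_g > 0 else np.zeros((3, n))
    accel = AccelTrace(t, ax + noise[0], ay + noise[1], az + noise[2])

    peak_v = peak_tilt_velocity(amp, protocol.speed_deg_s, a) if amp > 0 else 0.0
    return HeadMotionProfile(
        trace, accel, peak_v, a, (pre_hold_s, pre_hold_s + T)
    )


def _delayed_eye(head: AngularTrace, gain: float, latency_s: float) -> AngularTrace:
    shifted = np.interp(
        head.t - latency_s, head.t, head.angle_deg, left=head.angle_deg[0]
    )
    return AngularTrace(head.t, -gain * shifted, head.plane, FrameOfReference.EYE_IN_HEAD)


def make_vor_eye_trace(
    head: HeadMotionProfile,
    truth: GroundTruth,
    noise_deg: float = 0.05,
    seed: int = 0,
) -> tuple[AngularTrace, GroundTruth]:
    """Compensatory eye trace realizing the requested dynamic and position gains.

    Slow-phase eye velocity is ``-dynamic_gain`` x head velocity delayed by a
    latency L; L is solved by one-dimensional root search on the noise-free
    trace so that the AUC-ratio position-gain estimator evaluates exactly to
    ``truth.position_gain`` over the active-movement window.  A position gain
    above the dynamic gain is infeasible (delay can only shrink the eye AUC).
    """
    if truth.position_gain > truth.dynamic_gain + 1e-12:
        raise InfeasibleConstructionError(
            "position gain cannot exceed dynamic gain in the delayed-eye model"
        )
    base = head.trace
    window = active_window(base)

    def pos_of(L: float) -> float:
        eye = _delayed_eye(base, truth.dynamic_gain, L)
        return position_gain(eye, base, window=window).gain

    if abs(truth.position_gain - truth.dynamic_gain) < 1e-12:
        latency = 0.0
    else:
        hi = 0.05
        while pos_of(hi) > truth.position_gain:
            hi *= 2.0
            if hi > 2.0:
                raise InfeasibleConstructionError(
                    "no latency below 2 s realizes the requested position gain"
                )
        latency = float(
            brentq(lambda L: pos_of(L) - truth.position_gain, 0.0, hi, xtol=1e-6)
        )

    eye = _delayed_eye(base, truth.dynamic_gain, latency)
    if noise_deg > 0:
        rng = np.random.default_rng(seed)
        eye = eye.copy(angle_deg=eye.angle_deg + rng.normal(0, noise_deg, eye.t.size))
    return eye, replace(truth, latency_s=latency)


def _truncnorm_rvs(mean: float, rng: np.random.Generator) -> float:
    """Truncated-normal event jitter: 30% relative SD, bounds [0.5x, 1.5x]."""
    sd = _JITTER_REL_SD * mean
    lo, hi = _JITTER_BOUNDS[0] * mean, _JITTER_BOUNDS[1] * mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def insert_nystagmus(
    eye: AngularTrace,
    truth: GroundTruth,
    orbit_limit_deg: float = 2.0,
    seed: int = 0,
) -> tuple[AngularTrace, PhaseSegmentation, GroundTruth]:
    """Insert quick-phase resetting movements into a slow-phase eye trace.

    Whenever eye eccentricity exceeds ``orbit_limit_deg``, a constant-velocity
    reset is inserted toward the center (the head-movement direction,
    opposite the slow phase) with duration ~ TruncNormal(quick_duration_s,
    30% SD, [0.5x, 1.5x]) snapped to the sample grid and amplitude drawn the
    same way.  The slow-phase velocity is suspended during the reset and
    unchanged outside it.  Returns the modified trace, the ground-truth
    segmentation, and the truth updated with per-event durations/amplitudes.
    """
    if orbit_limit_deg <= truth.quick_amplitude_deg / 2:
        raise InvalidParameterError(
            "orbit limit must exceed half the quick-phase amplitude"
        )
    rng = np.random.default_rng(seed)
    x = eye.angle_deg
    n = x.size
    fs = eye.sample_rate
    out = x.copy()
    offset = 0.0
    quick_idx: list[tuple[int, int]] = []
    durations: list[float] = []
    amplitudes: list[float] = []
    i = 1
    while i < n:
        out[i] = x[i] + offset
        if abs(out[i]) > orbit_limit_deg:
            d = _truncnorm_rvs(truth.quick_duration_s, rng)
            a = _truncnorm_rvs(truth.quick_amplitude_deg, rng)
            k = max(1, int(round(d * fs)))
            if i + k >= n:
                break
            direction = -np.sign(out[i])
            for j in range(1, k + 1):
                out[i + j] = out[i] + direction * a * j / k
            offset = out[i + k] - x[i + k]
            quick_idx.append((i, i + k))
            durations.append(k / fs)
            amplitudes.append(a)
            i += k
        i += 1

    phases: list[Phase] = []
    cursor = float(eye.t[0])
    for a_i, b_i in quick_idx:
        start, end = float(eye.t[a_i]), float(eye.t[b_i])
        if start > cursor + 1e-12:
            phases.append(Phase("slow", cursor, start))
        phases.append(Phase("quick", start, end))
        cursor = end
    if cursor < float(eye.t[-1]) - 1e-12:
        phases.append(Phase("slow", cursor, float(eye.t[-1])))
    seg = PhaseSegmentation(phases or [Phase("slow", float(eye.t[0]), float(eye.t[-1]))], 1)
    new_truth = replace(
        truth,
        quick_durations_s=np.asarray(durations),
        quick_amplitudes_deg=np.asarray(amplitudes),
    )
    return eye.copy(angle_deg=out), seg, new_truth


def _angle_to_px(theta_deg: np.ndarray, cal: Calibration, axis: str) -> np.ndarray:
    """Inverse of :func:`gazestab.kinematics.pixels_to_degrees`."""
    th = np.asarray(theta_deg, float)
    if axis == "y" and cal.y_axis_down:
        th = -th
    rad = np.radians(th)
    if cal.angle_mode == "chord":
        d_mm = cal.eye_diameter_mm * np.sin(rad / 2.0)
    else:
        d_mm = cal.eye_diameter_mm * rad / 2.0
    return d_mm / cal.mm_per_px


def make_tracker_table(
    eye: AngularTrace,
    calibration: Calibration | None = None,
    jitter_px: float = 0.5,
    breathing_amp_px: float = 2.0,
    breathing_freq_hz: float = 0.5,
    seed: int = 0,
    axis: str = "x",
) -> TrackerTable:
    """Pose-tracker label table whose eye labels encode the given eye trace.

    Four eye labels sit on a circle around the pupil center, which moves by
    the pixel displacement corresponding to the eye angle; two body labels
    are static.  A slow sinusoidal breathing artifact is shared by all
    labels (so body subtraction can cancel it) and iid Gaussian jitter is
    added per label.  Likelihoods ~ Uniform(0.9, 1.0).
    """
    cal = calibration or Calibration(frame_rate=eye.sample_rate)
    rng = np.random.default_rng(seed)
    n = eye.t.size
    disp = _angle_to_px(eye.angle_deg, cal, axis)
    center = np.array([320.0, 240.0])
    breathing = breathing_amp_px * np.sin(2 * np.pi * breathing_freq_hz * eye.t)

    eye_offsets = 10.0 * np.array(
        [[np.cos(a), np.sin(a)] for a in np.radians([45, 135, 225, 315])]
    )
    body_pos = np.array([[100.0, 100.0], [120.0, 110.0]])

    cols: dict[tuple[str, str], np.ndarray] = {}
    ax_col = 0 if axis == "x" else 1
    for li, off in enumerate(eye_offsets):
        base = np.tile(center + off, (n, 1))
        base[:, ax_col] += disp
        base += breathing[:, None]
        base += rng.normal(0, jitter_px, (n, 2)) if jitter_px > 0 else 0.0
        name = f"eye_{li + 1}"
        cols[(name, "x")] = base[:, 0]
        cols[(name, "y")] = base[:, 1]
        cols[(name, "likelihood")] = rng.uniform(0.9, 1.0, n)
    for bi, pos in enumerate(body_pos):
        base = np.tile(pos, (n, 1))
        base += breathing[:, None]
        base += rng.normal(0, jitter_px, (n, 2)) if jitter_px > 0 else 0.0
        name = f"body_{bi + 1}"
        cols[(name, "x")] = base[:, 0]
        cols[(name, "y")] = base[:, 1]
        cols[(name, "likelihood")] = rng.uniform(0.9, 1.0, n)

    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["bodyparts", "coords"])
    df.index.name = "frame"
    return TrackerTable(
        df,
        eye_labels=[f"eye_{i + 1}" for i in range(4)],
        body_labels=["body_1", "body_2"],
    )


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Greedy earliest-first thinning to pairwise gaps >= refractory."""
    kept: list[float] = []
    last = -np.inf
    for t in np.sort(times):
        if t - last >= refractory_s:
            kept.append(float(t))
            last = t
    return np.asarray(kept)


def make_emg_trial(
    protocol: StimulusProtocol,
    drive_gain: float = 1.0,
    baseline_rate: float = 2.0,
    seed: int = 0,
    sample_rate: float = 20000.0,
    noise_v: float = 5e-5,
    spike_amp_v: float = 5e-4,
    vis_latency_s: float = 0.15,
    vis_tau_s: float = 0.3,
    refractory_s: float = 0.002,
    animal_id: str = "animal-0",
    trial_id: str | None = None,
) -> tuple[EMGTrial, GroundTruth]:
    """Extraocular EMG trial with inhomogeneous-Poisson motor-unit spiking.

    rate(t) = baseline + drive_gain x drive(t), where the vestibular drive is
    the head speed during the dynamic tilt, the visual drive a decaying
    transient (time constant ``vis_tau_s``) starting ``vis_latency_s`` after
    stimulus onset with initial rate drive_gain x stimulus speed, and the
    combined condition the sum of the two (additivity is the generator's
    model of visuo-vestibular enhancement; the pipeline must not assume it).
    The VES and VIS components are drawn from substreams spawned from the
    seed, so the same-seed combined trial contains a superset of the
    vestibular-only spikes.  Spikes are thinned to a 2-ms refractory, each
    convolved with a biphasic 2-ms motor-unit waveform, plus Gaussian noise.
    """
    if drive_gain < 0 or baseline_rate < 0:
        raise InvalidParameterError("rates must be >= 0")
    a = _default_accel(protocol.speed_deg_s)
    T = tilt_duration(protocol.amplitude_deg, protocol.speed_deg_s, a)
    pre = 0.5
    post = 0.5
    total = pre + T + protocol.static_hold_s + post
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    dt = 1.0 / sample_rate

    epochs: dict[str, tuple[float, float]] = {"pre_stimulus": (0.0, pre)}
    has_ves = protocol.modality in (Modality.VES, Modality.VISVES)
    has_vis = protocol.modality in (Modality.VIS, Modality.VISVES)
    if has_ves:
        epochs["dynamic_tilt"] = (pre, pre + T)
        epochs["static_tilt"] = (pre + T, pre + T + protocol.static_hold_s)
    if has_vis:
        epochs["visual_stimulus"] = (pre, float(t[-1]))

    # component rates
    angle = _tilt_angle(t - pre, protocol.amplitude_deg, a, protocol.speed_deg_s)
    head_speed = np.abs(np.gradient(angle, dt))
    ves_rate = drive_gain * np.where((t >= pre) & (t <= pre + T), head_speed, 0.0)
    vis_onset = pre + vis_latency_s
    vis_rate = drive_gain * protocol.speed_deg_s * np.where(
        t >= vis_onset, np.exp(-(t - vis_onset) / vis_tau_s), 0.0
    )

    ss = np.random.SeedSequence([int(seed), 2201])
    rng_base, rng_ves, rng_vis, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    spike_sets = [t[rng_base.random(n) < baseline_rate * dt]]
    if has_ves:
        spike_sets.append(t[rng_ves.random(n) < np.clip(ves_rate * dt, 0, 1)])
    if has_vis:
        spike_sets.append(t[rng_vis.random(n) < np.clip(vis_rate * dt, 0, 1)])
    spikes = _thin_refractory(np.concatenate(spike_sets), refractory_s)

    # biphasic 2-ms waveform (derivative-of-Gaussian), peak = spike_amp_v
    sig = 0.0003
    tw = np.arange(-0.001, 0.001 + dt / 2, dt)
    w = -tw * np.exp(-(tw**2) / (2 * sig**2))
    w *= spike_amp_v / np.max(np.abs(w))
    v = np.zeros(n)
    idx = np.round(spikes * sample_rate).astype(int)
    half = len(w) // 2
    for i0 in idx:
        lo, hi = i0 - half, i0 - half + len(w)
        wlo, whi = max(0, -lo), len(w) - max(0, hi - n)
        v[max(0, lo) : min(n, hi)] += w[wlo:whi]
    v += rng_noise.normal(0, noise_v, n)

    trial = EMGTrial(
        t, v, sample_rate, protocol, epochs,
        animal_id=animal_id,
        trial_id=trial_id or f"{protocol.modality.value}-seed{seed}",
    )
    gains = PLANE_GAIN_DEFAULTS[protocol.plane]
    truth = GroundTruth(
        position_gain=gains[1], dynamic_gain=gains[0], spike_times=spikes
    )
    return trial, truth


def make_psp_train(
    n_pulses: int = 10,
    rate_hz: float = 10.0,
    amplitudes_mv: float | np.ndarray | None = None,
    tau_s: float = 0.05,
    noise_mv: float = 0.02,
    seed: int = 0,
    sample_rate: float = 10000.0,
    pre_s: float = 0.2,
    post_s: float = 0.3,
    resting_mv: float = -68.0,
) -> tuple[PSPTrain, GroundTruth]:
    """Evoked EPSP train: instant rise, exponential decay, linear superposition.

    Stored ground-truth amplitudes are the per-pulse *increments*, not the
    superposed peaks.  The default amplitude profile is slightly depressing
    (3% per pulse from 1 mV), matching sustained 10-pulse 10-Hz stimulation.
    """
    if rate_hz <= 0 or tau_s <= 0:
        raise InvalidParameterError("rate_hz and tau_s must be > 0")
    if n_pulses < 1:
        raise InvalidParameterError("need at least one pulse")
    if amplitudes_mv is None:
        amps = 1.0 * 0.97 ** np.arange(n_pulses)
    else:
        amps = np.broadcast_to(np.asarray(amplitudes_mv, float), (n_pulses,)).copy()
    # snap pulse times to the sample grid (stimulators are clock-locked)
    pulses = np.round((pre_s + np.arange(n_pulses) / rate_hz) * sample_rate) / sample_rate
    total = pre_s + n_pulses / rate_hz + post_s
    n = int(round(total * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    v = np.full(n, resting_mv)
    for tp, a in zip(pulses, amps):
        m = t >= tp
        v[m] += a * np.exp(-(t[m] - tp) / tau_s)
    if noise_mv > 0:
        v += np.random.default_rng(seed).normal(0, noise_mv, n)
    train = PSPTrain(t, v, pulses, resting_potential=resting_mv)
    truth = GroundTruth(epsp_amplitudes_mv=amps, decay_tau_s=tau_s)
    return train, truth


def make_swim_coupling(
    n_frames: int = 1200,
    swim_freq_hz: float = 1.0,
    frame_rate: float = 30.0,
    lag_frames: int = 7,
    coupling: float = 0.5,
    noise: float = 0.05,
    seed: int = 0,
) -> SwimCoupling:
    """Tail + binocular eye series with the eyes lagging the tail.

    tail = sinusoid + noise; each eye = -coupling x tail delayed by
    ``lag_frames`` plus independent noise, so the eye-tail correlation is
    negative and maximal in magnitude at the stored lag.
    """
    if lag_frames >= n_frames / 10:
        raise InvalidParameterError("lag_frames must be < n_frames/10")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    clean_tail = np.sin(2 * np.pi * swim_freq_hz * t)
    tail = clean_tail + (rng.normal(0, noise, n_frames) if noise > 0 else 0.0)
    delayed = np.concatenate((np.full(lag_frames, clean_tail[0]), clean_tail))[:n_frames]
    eyes = []
    for _ in range(2):
        e = -coupling * delayed
        if noise > 0:
            e = e + rng.normal(0, noise * coupling, n_frames)
        eyes.append(e)
    return SwimCoupling(tail, eyes[0], eyes[1], frame_rate, lag_frames)


def vor_fixture(
    plane: Plane | str = Plane.ROLL,
    seed: int = 1,
    noise_deg: float = 0.05,
    amplitude_deg: float = 30.0,
    speed_deg_s: float = 120.0,
    sample_rate: float = 100.0,
) -> tuple[AngularTrace, HeadMotionProfile, GroundTruth]:
    """Canonical single-rotation VOR fixture with the plane's default gains."""
    plane = Plane(plane)
    dyn, pos = PLANE_GAIN_DEFAULTS[plane]
    protocol = StimulusProtocol(
        Modality.VES, plane, amplitude_deg, speed_deg_s, static_hold_s=1.0
    )
    head = make_head_motion(protocol, sample_rate, seed=seed, return_to_level=False)
    truth = GroundTruth(position_gain=pos, dynamic_gain=dyn)
    eye, truth = make_vor_eye_trace(head, truth, noise_deg=noise_deg, seed=seed)
    return eye, head, truth


def nystagmus_fixture(
    seed: int = 1,
    rotation_deg: float = 180.0,
    speed_deg_s: float = 137.0,
    sample_rate: float = 100.0,
    slow_gain: float = 0.05,
    orbit_limit_deg: float = 2.0,
    noise_deg: float = 0.01,
) -> tuple[AngularTrace, AngularTrace, PhaseSegmentation, GroundTruth]:
    """Full-rotation yaw fixture with nystagmus: (eye, head, truth seg, truth).

    The slow-phase gain here is deliberately small (default 0.05): during
    fast whole-body rotation the compensatory slow phase creeps while the
    quick phases stay near their stereotyped 0.024-s / 1.72-deg envelope,
    which is what produces the sawtooth.
    """
    protocol = StimulusProtocol(
        Modality.VES, Plane.YAW, rotation_deg, speed_deg_s, static_hold_s=0.5
    )
    head = make_head_motion(protocol, sample_rate, seed=seed, return_to_level=False)
    slow_eye = head.trace.copy(angle_deg=-slow_gain * head.trace.angle_deg)
    slow_eye.frame = FrameOfReference.EYE_IN_HEAD
    truth = GroundTruth(position_gain=slow_gain, dynamic_gain=slow_gain)
    eye, seg, truth = insert_nystagmus(slow_eye, truth, orbit_limit_deg, seed=seed)
    if noise_deg > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 77]))
        eye = eye.copy(angle_deg=eye.angle_deg + rng.normal(0, noise_deg, eye.t.size))
    return eye, head.trace, seg, truth
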