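"""Overlap-corrected EPSP amplitude measurement from stimulus-train responses.

During repetitive stimulation (e.g. 10 pulses at 10 Hz), each postsynaptic
potential rides on the decay of the previous ones, so the raw peak-to-rest
distance overestimates later amplitudes.  The decay after each response is
fitted with a single exponential ``A exp(-(t - t_peak)/tau) + C`` and
extrapolated to the next peak time; the next response's amplitude is its
peak minus that extrapolated baseline.  With a shared time constant this
correction is exact, because a sum of same-tau exponentials is itself a
single exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    FitFailureError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = ["PSPTrain", "EPSPMeasurements", "fit_decay", "measure_amplitudes"]

#: stimulus-artifact blanking after each pulse before searching for the peak
ARTIFACT_BLANK_S = 0.001


@dataclass
class PSPTrain:
    """Intracellular voltage trace with the stimulus pulse times."""

    t: np.ndarray
    v: np.ndarray  # millivolts
    pulse_times: np.ndarray
    resting_potential: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        self.pulse_times = np.asarray(self.pulse_times, float)
        if self.t.shape != self.v.shape:
            raise InvalidParameterError("t and v must have the same length")
        if self.pulse_times.size == 0:
            raise InvalidParameterError("at least one pulse is required")
        if np.any(np.diff(self.pulse_times) <= 0):
            raise InvalidParameterError("pulse times must be increasing")
        if self.pulse_times[0] < self.t[0] or self.pulse_times[-1] > self.t[-1]:
            raise InvalidParameterError("pulse times must lie within the trace")

    @property
    def sample_rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


@dataclass
class EPSPMeasurements:
    """Per-pulse overlap-corrected amplitudes; NaN marks a missing response."""

    raw_amplitudes_mv: np.ndarray
    normalized_amplitudes: np.ndarray
    tau_s: float
    fit_quality: float  # R^2 of the decay fits (mean over pulses)

    def __post_init__(self) -> None:
        self.raw_amplitudes_mv = np.asarray(self.raw_amplitudes_mv, float)
        self.normalized_amplitudes = np.asarray(self.normalized_amplitudes, float)
        if self.tau_s <= 0:
            raise InvalidParameterError("tau_s must be > 0")
        first = self.normalized_amplitudes[0]
        if np.isfinite(first) and not np.isclose(first, 1.0):
            raise InvalidParameterError("normalized amplitudes must start at 1")


def _peak_index(train: PSPTrain, pulse_index: int) -> int:
    """Index of the response peak in (pulse + blanking, next pulse]."""
    t_pulse = train.pulse_times[pulse_index]
    t_next = (
        train.pulse_times[pulse_index + 1]
        if pulse_index + 1 < train.pulse_times.size
        else t_pulse + np.median(np.diff(train.pulse_times)) if train.pulse_times.size > 1
        else train.t[-1]
    )
    t_next = min(t_next, train.t[-1])
    i0 = int(np.searchsorted(train.t, t_pulse + ARTIFACT_BLANK_S))
    i1 = int(np.searchsorted(train.t, t_next))
    if i1 <= i0:
        raise InsufficientDataError("empty peak-search window")
    return i0 + int(np.argmax(train.v[i0:i1]))


def fit_decay(
    train: PSPTrain, pulse_index: int
) -> tuple[float, Callable[[np.ndarray], np.ndarray], float]:
    """Fit ``A exp(-(t - t_peak)/tau) + C`` to one response's decay segment.

    The segment runs from this pulse's peak to the next pulse onset (or the
    trace end for the last pulse).  Returns ``(tau_s, extrapolate, r2)``
    where ``extrapolate(t)`` evaluates the fitted decay at arbitrary times.
    Raises :class:`FitFailureError` when the segment does not decay.
    """
    ip = _peak_index(train, pulse_index)
    t_end = (
        train.pulse_times[pulse_index + 1]
        if pulse_index + 1 < train.pulse_times.size
        else train.t[-1]
    )
    i1 = int(np.searchsorted(train.t, t_end))
    ts = train.t[ip:i1]
    vs = train.v[ip:i1]
    if ts.size < 5:
        raise InsufficientDataError(
            f"decay segment of pulse {pulse_index} has {ts.size} samples (<5)"
        )
    t_peak = ts[0]
    a0 = vs[0] - vs[-1]
    c0 = vs[-1]
    tau0 = max((ts[-1] - ts[0]) / 3.0, 1e-4)

    def model(t, A, tau, C):
        return A * np.exp(-(t - t_peak) / tau) + C

    try:
        popt, _ = curve_fit(
            model,
            ts,
            vs,
            p0=[max(a0, 1e-6), tau0, c0],
            bounds=([0.0, 1e-6, -np.inf], [np.inf, 10.0, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy detail
        raise FitFailureError(f"decay fit failed for pulse {pulse_index}: {exc}") from exc
    A, tau, C = popt
    resid = vs - model(ts, *popt)
    ss_tot = float(np.sum((vs - vs.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if A <= 1e-9 * (abs(C) + 1.0) or tau >= 9.9:
        raise FitFailureError(
            f"non-decaying segment for pulse {pulse_index}: A={A:.3g}, tau={tau:.3g}"
        )
    return float(tau), (lambda t: model(np.asarray(t, float), A, tau, C)), r2


def measure_amplitudes(train: PSPTrain, baseline_window_s: float = 0.05) -> EPSPMeasurements:
    """Overlap-corrected amplitude of every response in the train.

    Pulse 1 is measured from the pre-train baseline (median of the
    ``baseline_window_s`` before the first pulse).  Pulse i > 1 is measured
    from the extrapolated decay of the preceding fitted response evaluated at
    pulse i's onset.  Each response's own fitted decay is back-extrapolated
    to its pulse time, which undoes the decay lost during artifact blanking
    (the rise is modeled as instantaneous).  A response whose peak does not
    rise above its predicted baseline is flagged missing (NaN), not zero.
    """
    n = train.pulse_times.size
    t0 = train.pulse_times[0]
    pre = train.v[(train.t >= t0 - baseline_window_s) & (train.t < t0)]
    baseline0 = float(np.median(pre)) if pre.size else train.resting_potential

    raw = np.full(n, np.nan)
    r2s: list[float] = []
    tau_last = np.nan
    prev_extrap: Callable[[np.ndarray], np.ndarray] | None = None
    for i in range(n):
        tp = float(train.pulse_times[i])
        predicted = baseline0 if prev_extrap is None else float(prev_extrap(tp))
        try:
            tau, extrap, r2 = fit_decay(train, i)
        except (FitFailureError, InsufficientDataError):
            extrap = None
        if extrap is not None:
            amp = float(extrap(tp)) - predicted
        else:
            # no usable decay fit: fall back to the raw peak against the
            # previous extrapolation evaluated at the peak time
            ip = _peak_index(train, i)
            base_t = float(train.t[ip])
            predicted_pk = baseline0 if prev_extrap is None else float(prev_extrap(base_t))
            amp = float(train.v[ip]) - predicted_pk
        if amp > 0:
            raw[i] = amp
        if extrap is not None:
            prev_extrap = extrap
            tau_last = tau
            r2s.append(r2)
    if not np.isfinite(raw[0]):
        raise FitFailureError("no detectable response to the first pulse")
    normalized = raw / raw[0]
    tau = float(tau_last) if np.isfinite(tau_last) else 1e-3
    fitq = float(np.mean(r2s)) if r2s else float("nan")
    return EPSPMeasurements(raw, normalized, tau, fitq)
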