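"""Extraocular-muscle EMG quantification.

Per trial: rectification against a pre-stimulus baseline, robust threshold
spike detection, scalar response metrics (spike count, peak rectified
amplitude, time-to-peak, trapezoidal AUC), per-animal normalization, and
peristimulus spike-density maps in 100-ms bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import (
    InsufficientDataError,
    InvalidParameterError,
    StimulusProtocol,
    UndefinedResultError,
)

__all__ = [
    "EMGTrial",
    "SpikeTrain",
    "ResponseMetrics",
    "SpikeDensityMap",
    "rectify",
    "detect_spikes",
    "response_metrics",
    "default_window",
    "normalize_by_animal",
    "spike_density_map",
]

#: conversion from median absolute deviation to Gaussian sigma
_MAD_TO_SIGMA = 1.4826


@dataclass
class EMGTrial:
    """One voltage trace plus stimulus protocol and epoch boundaries.

    ``epochs`` maps names (``pre_stimulus``, ``dynamic_tilt``, ``static_tilt``,
    ``visual_stimulus``) to (start_s, end_s) intervals within the trace.
    """

    t: np.ndarray
    v: np.ndarray
    sample_rate: float
    protocol: StimulusProtocol
    epochs: dict[str, tuple[float, float]] = field(default_factory=dict)
    animal_id: str = "animal-0"
    trial_id: str = "trial-0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.v = np.asarray(self.v, float)
        if self.t.shape != self.v.shape:
            raise InvalidParameterError("t and v must have the same length")
        if self.t.size >= 2:
            dt = self.t[1] - self.t[0]
            if abs(dt * self.sample_rate - 1.0) > 1e-6:
                raise InvalidParameterError("sample_rate does not match t spacing")
        for name, (a, b) in self.epochs.items():
            if a < self.t[0] - 1e-9 or b > self.t[-1] + 1e-9 or b <= a:
                raise InvalidParameterError(f"epoch {name!r} outside trace support")

    def epoch_slice(self, name: str) -> slice:
        a, b = self.epochs[name]
        i0 = int(np.searchsorted(self.t, a - 1e-12))
        i1 = int(np.searchsorted(self.t, b + 1e-12))
        return slice(i0, i1)

    @property
    def stimulus_onset(self) -> float:
        """Start of the earliest non-baseline epoch."""
        starts = [a for name, (a, _) in self.epochs.items() if name != "pre_stimulus"]
        if not starts:
            raise InvalidParameterError("trial has no stimulus epochs")
        return min(starts)


@dataclass
class SpikeTrain:
    spike_times: np.ndarray
    threshold_used: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise InvalidParameterError("spike times must be strictly increasing")

    def count_in(self, window: tuple[float, float]) -> int:
        a, b = window
        return int(np.sum((self.spike_times >= a) & (self.spike_times <= b)))


@dataclass
class ResponseMetrics:
    n_spikes: int
    peak_amplitude: float
    time_to_peak_s: float
    auc: float
    window: tuple[float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        if min(self.n_spikes, self.peak_amplitude, self.auc) < 0:
            raise InvalidParameterError("response metrics must be >= 0")


@dataclass
class SpikeDensityMap:
    bin_edges: np.ndarray
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.values = np.asarray(self.values, float)
        if self.values.size + 1 != self.bin_edges.size:
            raise InvalidParameterError("need len(values)+1 bin edges")
        if self.normalized and self.values.size and not np.isclose(self.values.max(), 1.0):
            raise InvalidParameterError("normalized map must have max 1")


def _baseline(trial: EMGTrial) -> float:
    """Median of the pre-stimulus epoch (whole-trace median fallback)."""
    if "pre_stimulus" in trial.epochs:
        seg = trial.v[trial.epoch_slice("pre_stimulus")]
        if seg.size:
            return float(np.median(seg))
    warnings.warn("no pre-stimulus epoch: baseline from whole-trace median", stacklevel=3)
    return float(np.median(trial.v))


def rectify(trial: EMGTrial) -> np.ndarray:
    """Full-wave rectification around the pre-stimulus median baseline."""
    return np.abs(trial.v - _baseline(trial))


def detect_spikes(
    trial: EMGTrial, k_mad: float = 5.0, refractory_s: float = 0.002
) -> SpikeTrain:
    """Threshold-crossing spike detection on the rectified trace.

    Threshold = ``k_mad`` x robust noise sigma (1.4826 x MAD of the
    baseline-subtracted pre-stimulus signal).  Spikes are the suprathreshold
    local maxima of the rectified trace separated by at least
    ``refractory_s`` (larger peak wins), so the two phases of one biphasic
    motor-unit waveform yield a single spike and merged suprathreshold runs
    from near-coincident units still resolve into separate events.
    """
    if "pre_stimulus" not in trial.epochs:
        raise InsufficientDataError("spike detection needs a pre_stimulus epoch")
    pre = trial.epochs["pre_stimulus"]
    if pre[1] - pre[0] < 0.1:
        raise InsufficientDataError(">=100 ms of pre-stimulus signal required")
    base = _baseline(trial)
    noise = trial.v[trial.epoch_slice("pre_stimulus")] - base
    sigma = _MAD_TO_SIGMA * float(np.median(np.abs(noise - np.median(noise))))
    if sigma == 0:
        raise UndefinedResultError("flat pre-stimulus signal: noise scale degenerate")
    threshold = k_mad * sigma
    rect = np.abs(trial.v - base)
    distance = max(1, int(round(refractory_s * trial.sample_rate)))
    peaks, _ = find_peaks(rect, height=threshold, distance=distance)
    return SpikeTrain(
        trial.t[peaks],
        threshold,
        {"k_mad": k_mad, "refractory_s": refractory_s, "sigma": sigma},
    )


def default_window(trial: EMGTrial) -> tuple[float, float]:
    """Default analysis window: stimulus onset to end of static tilt when the
    trial has a vestibular component, else onset + 2 s (visual-only)."""
    onset = trial.stimulus_onset
    if "static_tilt" in trial.epochs:
        return (onset, trial.epochs["static_tilt"][1])
    return (onset, min(onset + 2.0, float(trial.t[-1])))


def response_metrics(
    trial: EMGTrial,
    spikes: SpikeTrain,
    window: tuple[float, float] | None = None,
    smooth_s: float = 0.010,
) -> ResponseMetrics:
    """Scalar response summary over the analysis window.

    AUC is the trapezoidal integral of the rectified trace; peak amplitude is
    the maximum of the rectified trace; time-to-peak is measured from
    stimulus onset on a 10-ms moving-average-smoothed copy so a single noise
    sample cannot define the peak.
    """
    if window is None:
        window = default_window(trial)
    a, b = window
    sel = (trial.t >= a) & (trial.t <= b)
    if sel.sum() < 2:
        raise InvalidParameterError("empty or single-sample analysis window")
    rect = rectify(trial)
    tw, rw = trial.t[sel], rect[sel]
    auc = float(np.trapezoid(rw, tw))
    peak = float(np.max(rw))
    n = max(1, int(round(smooth_s * trial.sample_rate)))
    smooth = np.convolve(rw, np.ones(n) / n, mode="same")
    t_peak = float(tw[int(np.argmax(smooth))] - trial.stimulus_onset)
    return ResponseMetrics(spikes.count_in(window), peak, max(t_peak, 0.0), auc, window)


def normalize_by_animal(
    metrics: pd.DataFrame, value_cols: tuple[str, ...] = ("n_spikes", "peak_amplitude", "auc")
) -> pd.DataFrame:
    """Divide each metric by the per-animal, per-modality maximum.

    ``metrics`` is tidy with at least ``animal_id`` and ``modality`` columns.
    Within each (animal, modality) group every value column is divided by its
    group maximum, so each group's maximum becomes 1 and values are
    comparable across preparations with different signal strengths.
    Idempotent.  Raises :class:`UndefinedResultError` for an all-zero group.
    """
    out = metrics.copy()
    out[list(value_cols)] = out[list(value_cols)].astype(float)
    for (animal, modality), grp in metrics.groupby(["animal_id", "modality"]):
        for col in value_cols:
            m = grp[col].max()
            if m <= 0:
                if (grp[col] == 0).all():
                    raise UndefinedResultError(
                        f"all-zero group animal={animal} modality={modality} col={col}"
                    )
                raise UndefinedResultError(
                    f"non-positive maximum in group animal={animal} modality={modality}"
                )
            out.loc[grp.index, col] = grp[col] / m
    return out


def spike_density_map(
    spike_trains: list[SpikeTrain] | list[np.ndarray],
    bin_s: float = 0.1,
    t0: float = 0.0,
    t1: float | None = None,
) -> SpikeDensityMap:
    """Trial-averaged, maximum-normalized peristimulus spike density.

    Spike counts are histogrammed into ``bin_s`` bins aligned at the stimulus
    onset ``t0``, averaged across trials, then divided by the maximum bin so
    the densest cluster maps to 1.  With no spikes anywhere the all-zero map
    is returned with ``normalized=False`` (no division by zero).
    """
    if not spike_trains:
        raise InvalidParameterError("need at least one spike train")
    arrays = [
        st.spike_times if isinstance(st, SpikeTrain) else np.asarray(st, float)
        for st in spike_trains
    ]
    if t1 is None:
        t1 = max((a.max() for a in arrays if a.size), default=t0 + bin_s)
    n_bins = max(1, int(np.ceil((t1 - t0) / bin_s - 1e-9)))
    edges = t0 + bin_s * np.arange(n_bins + 1)
    counts = np.stack([np.histogram(a, bins=edges)[0] for a in arrays]).astype(float)
    mean = counts.mean(axis=0)
    peak = mean.max()
    if peak == 0:
        return SpikeDensityMap(edges, mean, normalized=False)
    return SpikeDensityMap(edges, mean / peak, normalized=True)
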