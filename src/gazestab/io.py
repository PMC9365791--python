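"""Readers and writers for the CSV dialects the pipeline consumes.

Formats
-------
* Tracker CSV: the markerless-tracker dialect with three header rows
  (scorer / bodyparts / coords) and x, y, likelihood columns per label,
  one row per video frame.
* Angular-trace CSV: ``t, angle_deg`` plus ``# plane:`` / ``# frame:``
  comment headers.
* Accelerometer CSV: ``t, ax, ay, az`` in g.
* EMG: ``t, v`` CSV plus an epochs JSON mapping name -> [start_s, end_s].
* PSP: ``t, v`` CSV plus a pulse-times JSON list.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AccelTrace,
    AngularTrace,
    FormatError,
    FrameOfReference,
    Plane,
    StimulusProtocol,
)
from .emg import EMGTrial
from .kinematics import TrackerTable
from .psp import PSPTrain

__all__ = [
    "read_tracker_csv",
    "write_tracker_csv",
    "read_angular_trace",
    "write_angular_trace",
    "read_accel_trace",
    "write_accel_trace",
    "read_emg_trial",
    "write_emg_trial",
    "read_psp_train",
    "write_psp_train",
]


def read_tracker_csv(path, eye_labels=None, body_labels=None) -> TrackerTable:
    """Parse a three-header-row tracker CSV into a :class:`TrackerTable`."""
    path = Path(path)
    with open(path) as fh:
        head = [fh.readline().rstrip("\n") for _ in range(3)]
    expected = ("scorer", "bodyparts", "coords")
    for row, name in zip(head, expected):
        first = row.split(",")[0].strip().lower()
        if first != name:
            raise FormatError(
                f"{path.name}: expected the 3-header-row tracker dialect "
                f"(scorer / bodyparts / coords); header row starts with {first!r}"
            )
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    scorer = df.columns.get_level_values(0)[0]
    df.columns = df.columns.droplevel(0)
    bad = df.apply(lambda col: pd.to_numeric(col, errors="coerce")).isna() & df.notna()
    if bad.to_numpy().any():
        frame = df.index[bad.any(axis=1)][0]
        raise FormatError(f"{path.name}: non-numeric cell at frame {frame}")
    df = df.astype(float)
    labels = list(dict.fromkeys(df.columns.get_level_values(0)))
    if body_labels is None:
        body_labels = [l for l in labels if l.lower().startswith("body")]
    if eye_labels is None:
        eye_labels = [l for l in labels if l not in body_labels]
    return TrackerTable(df, list(eye_labels), list(body_labels), scorer=scorer)


def write_tracker_csv(table: TrackerTable, path) -> None:
    df = table.data.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(table.scorer, bp, c) for bp, c in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path)


def write_angular_trace(trace: AngularTrace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# plane: {trace.plane.value}\n")
        fh.write(f"# frame: {trace.frame.value}\n")
        pd.DataFrame({"t": trace.t, "angle_deg": trace.angle_deg}).to_csv(fh, index=False)


def read_angular_trace(path) -> AngularTrace:
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if "t" not in df.columns or "angle_deg" not in df.columns:
        raise FormatError(f"{path}: expected columns t, angle_deg")
    return AngularTrace(
        df["t"].to_numpy(),
        df["angle_deg"].to_numpy(),
        Plane(meta.get("plane", "roll")),
        FrameOfReference(meta.get("frame", "eye_in_head")),
    )


def write_accel_trace(accel: AccelTrace, path) -> None:
    pd.DataFrame({"t": accel.t, "ax": accel.ax, "ay": accel.ay, "az": accel.az}).to_csv(
        path, index=False
    )


def read_accel_trace(path) -> AccelTrace:
    df = pd.read_csv(path)
    missing = {"t", "ax", "ay", "az"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return AccelTrace(*(df[c].to_numpy() for c in ("t", "ax", "ay", "az")))


def write_emg_trial(trial: EMGTrial, trace_path, epochs_path) -> None:
    pd.DataFrame({"t": trial.t, "v": trial.v}).to_csv(trace_path, index=False)
    payload = {
        "epochs": {k: list(v) for k, v in trial.epochs.items()},
        "sample_rate": trial.sample_rate,
        "animal_id": trial.animal_id,
        "trial_id": trial.trial_id,
        "protocol": {
            "modality": trial.protocol.modality.value,
            "plane": trial.protocol.plane.value,
            "amplitude_deg": trial.protocol.amplitude_deg,
            "speed_deg_s": trial.protocol.speed_deg_s,
            "static_hold_s": trial.protocol.static_hold_s,
        },
    }
    Path(epochs_path).write_text(json.dumps(payload, indent=1))


def read_emg_trial(trace_path, epochs_path) -> EMGTrial:
    df = pd.read_csv(trace_path)
    if not {"t", "v"} <= set(df.columns):
        raise FormatError(f"{trace_path}: expected columns t, v")
    payload = json.loads(Path(epochs_path).read_text())
    proto = payload.get("protocol", {})
    protocol = StimulusProtocol(
        proto.get("modality", "VES"),
        proto.get("plane", "roll"),
        proto.get("amplitude_deg", 22.7),
        proto.get("speed_deg_s", 48.7),
        proto.get("static_hold_s", 1.0),
    )
    return EMGTrial(
        df["t"].to_numpy(),
        df["v"].to_numpy(),
        payload["sample_rate"],
        protocol,
        {k: tuple(v) for k, v in payload["epochs"].items()},
        animal_id=payload.get("animal_id", "animal-0"),
        trial_id=payload.get("trial_id", "trial-0"),
    )


def write_psp_train(train: PSPTrain, trace_path, pulses_path) -> None:
    pd.DataFrame({"t": train.t, "v": train.v}).to_csv(trace_path, index=False)
    Path(pulses_path).write_text(
        json.dumps(
            {
                "pulse_times": train.pulse_times.tolist(),
                "resting_potential": train.resting_potential,
            }
        )
    )


def read_psp_train(trace_path, pulses_path) -> PSPTrain:
    df = pd.read_csv(trace_path)
    if not {"t", "v"} <= set(df.columns):
        raise FormatError(f"{trace_path}: expected columns t, v")
    payload = json.loads(Path(pulses_path).read_text())
    return PSPTrain(
        df["t"].to_numpy(),
        df["v"].to_numpy(),
        np.asarray(payload["pulse_times"], float),
        resting_potential=payload.get("resting_potential", 0.0),
    )
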