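"""Trial time-series and dataset-manifest I/O.

Trials are stored in the classic OpenSim text-storage dialect (.sto/.mot):
a small ``key=value`` header terminated by an ``endheader`` line, a
tab-separated column-label line whose first column is ``time``, then the
numeric body.  Angles are stored in degrees (``inDegrees=yes``) and time is
always column 0, never a feature channel.  A dataset manifest (YAML) binds
trial files to subjects, movements, roles and MVIC normalization references.

EMG (1,500 Hz) and kinematics/torque (100 Hz) are stored as *separate*
trials sharing t = 0; alignment happens downstream in
:mod:`kneetorque.emg_processing`.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: The seven instrumented muscles, in canonical channel order.
MUSCLES = (
    "gastroc_med",
    "gastroc_lat",
    "biceps_fem",
    "semitend",
    "rectus_fem",
    "vastus_med",
    "vastus_lat",
)

#: +1 = knee extensor, -1 = knee flexor (extension torque is positive).
MUSCLE_ACTION_SIGN = {
    "gastroc_med": -1,
    "gastroc_lat": -1,
    "biceps_fem": -1,
    "semitend": -1,
    "rectus_fem": +1,
    "vastus_med": +1,
    "vastus_lat": +1,
}

GAIT_MOVEMENTS = ("gait_slow", "gait_self", "gait_fast")
ISO_MOVEMENTS = ("iso_30", "iso_45", "iso_60", "iso_75", "iso_90")
MOVEMENTS = GAIT_MOVEMENTS + ISO_MOVEMENTS + ("mvic",)

TRIAL_ROLES = ("train", "test", "mvic_reference")

ANGLE_CHANNEL = "knee_angle_deg"
TORQUE_CHANNEL = "knee_torque_nm"

# Time-grid spacing tolerance (seconds) when validating a trial.
TIME_SPACING_TOL_S = 1e-6


class StorageFormatError(ValueError):
    """Raised when a storage file's header cannot be parsed."""


class StorageIntegrityError(ValueError):
    """Raised when declared and actual row/column counts disagree."""


class ManifestError(ValueError):
    """Raised when a dataset manifest fails validation."""


@dataclass
class TimeSeriesTrial:
    """One recorded or simulated trial: labelled channels on a shared clock."""

    subject_id: str
    movement: str
    sampling_rate_hz: float
    channel_names: list[str]
    time_s: np.ndarray
    data: np.ndarray
    name: str = "trial"

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        self.channel_names = list(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.movement not in MOVEMENTS:
            raise ValueError(
                f"unknown movement {self.movement!r}; expected one of {MOVEMENTS}"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.data.shape[0] != self.time_s.shape[0]:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but time has "
                f"{self.time_s.shape[0]} samples"
            )
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"data has {self.data.shape[1]} columns but "
                f"{len(self.channel_names)} channel names were given"
            )
        dt = np.diff(self.time_s)
        if self.time_s.size > 1:
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(dt - 1.0 / self.sampling_rate_hz)) > TIME_SPACING_TOL_S:
                raise ValueError(
                    "time spacing inconsistent with sampling_rate_hz "
                    f"({self.sampling_rate_hz} Hz)"
                )

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) if self.time_s.size else 0.0

    def channel(self, name: str) -> np.ndarray:
        try:
            j = self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"trial has no channel {name!r}") from None
        return self.data[:, j]


# ---------------------------------------------------------------------------
# OpenSim text storage (.sto / .mot)
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # %.17g round-trips float64 exactly and is deterministic.
    return format(float(x), ".17g")


def write_sto(trial: TimeSeriesTrial, path: str | os.PathLike) -> None:
    """Write a trial as classic OpenSim text storage (deterministic bytes)."""
    trial.validate()
    n_rows = trial.time_s.shape[0]
    n_cols = 1 + trial.data.shape[1]  # time column included
    buf = io.StringIO()
    buf.write(f"{trial.name}\n")
    buf.write("version=1\n")
    buf.write(f"nRows={n_rows}\n")
    buf.write(f"nColumns={n_cols}\n")
    buf.write("inDegrees=yes\n")
    buf.write(f"subject_id={trial.subject_id}\n")
    buf.write(f"movement={trial.movement}\n")
    buf.write(f"sampling_rate_hz={_fmt(trial.sampling_rate_hz)}\n")
    buf.write("endheader\n")
    buf.write("\t".join(["time"] + trial.channel_names) + "\n")
    for i in range(n_rows):
        row = [_fmt(trial.time_s[i])] + [_fmt(v) for v in trial.data[i]]
        buf.write("\t".join(row) + "\n")
    Path(path).write_text(buf.getvalue())


def read_sto(path: str | os.PathLike) -> TimeSeriesTrial:
    """Read a trial from OpenSim text storage.

    Raises :class:`StorageFormatError` on malformed headers (naming the
    offending line) and :class:`StorageIntegrityError` when declared and
    actual row/column counts disagree.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    name = None
    end_idx = None
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped == "endheader":
            end_idx = i
            break
        if "=" in stripped:
            key, _, value = stripped.partition("=")
            header[key.strip()] = value.strip()
        elif stripped and name is None:
            name = stripped
        elif stripped:
            raise StorageFormatError(f"{path}: unparseable header line {i + 1}: {line!r}")
    if end_idx is None:
        raise StorageFormatError(f"{path}: missing 'endheader' terminator")
    for key in ("nRows", "nColumns"):
        if key not in header:
            raise StorageFormatError(f"{path}: header missing {key}")
    try:
        n_rows = int(header["nRows"])
        n_cols = int(header["nColumns"])
    except ValueError as exc:
        raise StorageFormatError(f"{path}: non-integer row/column count") from exc

    body = [ln for ln in lines[end_idx + 1 :] if ln.strip()]
    if not body:
        raise StorageFormatError(f"{path}: missing column-label line")
    labels = body[0].split("\t")
    if labels[0] != "time":
        raise StorageFormatError(f"{path}: first column label must be 'time'")
    if len(labels) != n_cols:
        raise StorageIntegrityError(
            f"{path}: header declares {n_cols} columns but label line has {len(labels)}"
        )
    data_lines = body[1:]
    if len(data_lines) != n_rows:
        raise StorageIntegrityError(
            f"{path}: header declares {n_rows} rows but body has {len(data_lines)}"
        )
    values = np.empty((n_rows, n_cols), dtype=float)
    for i, line in enumerate(data_lines):
        parts = line.split("\t")
        if len(parts) != n_cols:
            raise StorageIntegrityError(
                f"{path}: row {i + 1} has {len(parts)} fields, expected {n_cols}"
            )
        values[i] = [float(p) for p in parts]

    time_s = values[:, 0]
    if "sampling_rate_hz" in header:
        fs = float(header["sampling_rate_hz"])
    elif n_rows > 1:
        fs = 1.0 / float(np.median(np.diff(time_s)))
    else:
        fs = 1.0
    return TimeSeriesTrial(
        subject_id=header.get("subject_id", "unknown"),
        movement=header.get("movement", "mvic"),
        sampling_rate_hz=fs,
        channel_names=labels[1:],
        time_s=time_s,
        data=values[:, 1:],
        name=name or "trial",
    )


# ---------------------------------------------------------------------------
# CSV (header row: time_s, then channels)
# ---------------------------------------------------------------------------

def write_csv_trial(trial: TimeSeriesTrial, path: str | os.PathLike) -> None:
    df = pd.DataFrame(trial.data, columns=trial.channel_names)
    df.insert(0, "time_s", trial.time_s)
    df.to_csv(path, index=False, float_format="%.17g")


def read_csv_trial(
    path: str | os.PathLike,
    subject_id: str = "unknown",
    movement: str = "mvic",
    sampling_rate_hz: float | None = None,
) -> TimeSeriesTrial:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise StorageFormatError(f"{path}: CSV must have a 'time_s' column")
    time_s = df["time_s"].to_numpy(float)
    if sampling_rate_hz is None:
        sampling_rate_hz = 1.0 / float(np.median(np.diff(time_s))) if len(time_s) > 1 else 1.0
    channels = [c for c in df.columns if c != "time_s"]
    return TimeSeriesTrial(
        subject_id=subject_id,
        movement=movement,
        sampling_rate_hz=sampling_rate_hz,
        channel_names=channels,
        time_s=time_s,
        data=df[channels].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# Dataset manifest
# ---------------------------------------------------------------------------

@dataclass
class SubjectInfo:
    subject_id: str
    body_mass_kg: float

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ManifestError(f"subject {self.subject_id}: nonpositive body mass")


@dataclass
class TrialEntry:
    trial_id: str
    subject_id: str
    movement: str
    role: str
    emg_path: str
    kinematics_path: str | None = None


@dataclass
class DatasetManifest:
    subjects: list[SubjectInfo]
    trials: list[TrialEntry]

    def subject(self, subject_id: str) -> SubjectInfo:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise ManifestError(f"unknown subject {subject_id!r}")

    def body_mass(self, subject_id: str) -> float:
        return self.subject(subject_id).body_mass_kg

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate subject ids in manifest")
        known = set(ids)
        dangling = sorted({t.subject_id for t in self.trials} - known)
        if dangling:
            raise ManifestError(f"trials reference unknown subjects: {dangling}")
        for t in self.trials:
            if t.movement not in MOVEMENTS:
                raise ManifestError(f"trial {t.trial_id}: unknown movement {t.movement!r}")
            if t.role not in TRIAL_ROLES:
                raise ManifestError(f"trial {t.trial_id}: unknown role {t.role!r}")
        for sid in ids:
            refs = [t for t in self.trials if t.subject_id == sid and t.role == "mvic_reference"]
            if not refs:
                raise ManifestError(f"subject {sid} has no mvic_reference trial")


@dataclass
class TrialRecord:
    """A manifest trial with its time series loaded."""

    trial_id: str
    subject_id: str
    movement: str
    role: str
    emg: TimeSeriesTrial
    kinematics: TimeSeriesTrial | None = None


def save_manifest(manifest: DatasetManifest, path: str | os.PathLike) -> None:
    doc = {
        "subjects": [
            {"subject_id": s.subject_id, "body_mass_kg": float(s.body_mass_kg)}
            for s in manifest.subjects
        ],
        "trials": [
            {
                "trial_id": t.trial_id,
                "subject_id": t.subject_id,
                "movement": t.movement,
                "role": t.role,
                "emg_path": t.emg_path,
                "kinematics_path": t.kinematics_path,
            }
            for t in manifest.trials
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_manifest(path: str | os.PathLike) -> DatasetManifest:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or "subjects" not in doc or "trials" not in doc:
        raise ManifestError(f"{path}: manifest must define 'subjects' and 'trials'")
    manifest = DatasetManifest(
        subjects=[SubjectInfo(str(s["subject_id"]), float(s["body_mass_kg"])) for s in doc["subjects"]],
        trials=[
            TrialEntry(
                trial_id=str(t.get("trial_id", f"trial{i:03d}")),
                subject_id=str(t["subject_id"]),
                movement=str(t["movement"]),
                role=str(t.get("role", "train")),
                emg_path=str(t["emg_path"]),
                kinematics_path=(str(t["kinematics_path"]) if t.get("kinematics_path") else None),
            )
            for i, t in enumerate(doc["trials"])
        ],
    )
    manifest.validate()
    return manifest


def load_manifest(path: str | os.PathLike) -> tuple[DatasetManifest, list[TrialRecord]]:
    """Read a manifest and load every referenced trial, fully validated.

    Channel order is taken from the files and never reordered; paths are
    resolved relative to the manifest's directory.
    """
    path = Path(path)
    manifest = read_manifest(path)
    base = path.parent
    records: list[TrialRecord] = []
    for t in manifest.trials:
        emg = read_sto(base / t.emg_path)
        kin = read_sto(base / t.kinematics_path) if t.kinematics_path else None
        if emg.subject_id != t.subject_id:
            raise ManifestError(
                f"trial {t.trial_id}: file subject {emg.subject_id!r} != manifest "
                f"subject {t.subject_id!r}"
            )
        records.append(
            TrialRecord(
                trial_id=t.trial_id,
                subject_id=t.subject_id,
                movement=t.movement,
                role=t.role,
                emg=emg,
                kinematics=kin,
            )
        )
    return manifest, records
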