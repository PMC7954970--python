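"""Landmark model, coordinate conventions and file I/O for skeleton recordings.

The in-memory containers mirror what a Kinect-V2-class markerless capture
system delivers: per frame, 3D positions of 25 named anatomical landmarks at
a nominal 30 Hz.  The coordinate frame is fixed throughout the package:

* **X** — medio-lateral, subject's right positive,
* **Y** — vertical, up positive,
* **Z** — anterior-posterior, from the camera into the scene positive, so a
  subject walking toward the camera has decreasing Z.

All internal quantities are meters and seconds; reporting units (cm, deg,
steps/min) appear only in :class:`ParameterVector` and the report builders.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AXIAL_LANDMARKS",
    "LANDMARKS",
    "LandmarkSet",
    "SkeletonSequence",
    "TaskRecording",
    "SubjectRecord",
    "ParameterVector",
    "PARAMETER_DEFS",
    "PARAMETER_NAMES",
    "PARAMETER_UNITS",
    "TASKS",
    "TASK_CUE_COUNTS",
    "TASK_PARAMETERS",
    "SkeletonFormatError",
    "read_skeleton_csv",
    "write_skeleton_csv",
    "read_subjects_csv",
    "write_subjects_csv",
    "parameter_table_to_tidy",
    "tidy_to_parameter_table",
]


class SkeletonFormatError(ValueError):
    """Raised when a skeleton or subjects file violates the expected dialect."""


# --------------------------------------------------------------------------
# Landmark model
# --------------------------------------------------------------------------

AXIAL_LANDMARKS = ("spine_base", "spine_mid", "spine_shoulder", "neck", "head")

_SIDED = ("shoulder", "elbow", "wrist", "hand", "hand_tip", "thumb",
          "hip", "knee", "ankle", "foot")

#: Fixed landmark order used by every array in the package and by the CSV dialect.
LANDMARKS: tuple[str, ...] = (
    AXIAL_LANDMARKS
    + tuple(f"left_{part}" for part in _SIDED)
    + tuple(f"right_{part}" for part in _SIDED)
)


class LandmarkSet:
    """The 25-landmark vocabulary with total name lookup and left/right pairing."""

    names: tuple[str, ...] = LANDMARKS

    _INDEX: Mapping[str, int] = {name: i for i, name in enumerate(LANDMARKS)}

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self._INDEX

    def index(self, name: str) -> int:
        """Positional index of a landmark; unknown names are an error."""
        try:
            return self._INDEX[name]
        except KeyError:
            raise KeyError(f"unknown landmark {name!r}") from None

    def mirror(self, name: str) -> str:
        """Return the contralateral landmark; axial landmarks map to themselves."""
        self.index(name)
        if name.startswith("left_"):
            return "right_" + name[5:]
        if name.startswith("right_"):
            return "left_" + name[6:]
        return name


LANDMARK_SET = LandmarkSet()


# --------------------------------------------------------------------------
# Task vocabulary
# --------------------------------------------------------------------------

TASKS = ("POCO", "SCSW", "SMSW", "SLW", "SAS", "SIP")

#: Number of audio cues each task carries.  POCO's single cue separates the
#: eyes-open from the eyes-closed stance phase; SAS has stand-up and sit-down
#: commands; the walks and stepping in place are started by an (unrecorded) cue.
TASK_CUE_COUNTS = {"POCO": 1, "SCSW": 0, "SMSW": 0, "SLW": 0, "SAS": 2, "SIP": 0}

#: Tasks with two immediate measurement repetitions (three recordings per subject).
REPEATED_TASKS = ("SCSW", "SMSW", "SLW", "SAS")

#: Kinect-V2-like admissible mean frame interval, seconds.
FRAME_INTERVAL_BOUNDS = (1.0 / 40.0, 1.0 / 20.0)


# --------------------------------------------------------------------------
# Sequences and recordings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SkeletonSequence:
    """Timestamped 3D positions of the 25 landmarks.

    Parameters
    ----------
    timestamps : (n,) array, seconds, strictly increasing.
    positions : (n, 25, 3) array, meters, ordered as :data:`LANDMARKS` with
        columns (X, Y, Z).
    validate_rate : bool
        Enforce the Kinect-like mean frame interval band.  Property tests that
        rescale time may switch this off; file ingest never does.
    """

    timestamps: np.ndarray
    positions: np.ndarray
    validate_rate: bool = True

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "positions", pos)
        if ts.ndim != 1 or ts.size < 2:
            raise SkeletonFormatError("no frames: need at least 2 timestamps")
        if pos.shape != (ts.size, len(LANDMARKS), 3):
            raise SkeletonFormatError(
                f"positions shape {pos.shape} does not match "
                f"({ts.size}, {len(LANDMARKS)}, 3)"
            )
        if not np.all(np.isfinite(ts)):
            raise SkeletonFormatError("non-finite timestamp")
        if np.any(np.diff(ts) <= 0):
            i = int(np.argmax(np.diff(ts) <= 0))
            raise SkeletonFormatError(f"non-monotonic timestamps at frame {i + 1}")
        if not np.all(np.isfinite(pos)):
            raise SkeletonFormatError("non-finite position")
        if self.validate_rate:
            lo, hi = FRAME_INTERVAL_BOUNDS
            dt = float(np.mean(np.diff(ts)))
            if not (lo <= dt <= hi):
                raise SkeletonFormatError(
                    f"mean frame interval {dt:.4f} s outside [{lo:.4f}, {hi:.4f}] s"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def mean_dt(self) -> float:
        return float(np.mean(np.diff(self.timestamps)))

    def landmark(self, name: str) -> np.ndarray:
        """(n, 3) positions of one landmark."""
        return self.positions[:, LANDMARK_SET.index(name), :]

    def translated(self, offset: Sequence[float]) -> "SkeletonSequence":
        """Rigidly translate the whole scene (used by invariance tests)."""
        off = np.asarray(offset, dtype=float).reshape(1, 1, 3)
        return SkeletonSequence(self.timestamps, self.positions + off,
                                validate_rate=self.validate_rate)

    def time_shifted(self, delta: float) -> "SkeletonSequence":
        return SkeletonSequence(self.timestamps + delta, self.positions,
                                validate_rate=self.validate_rate)

    def time_scaled(self, c: float) -> "SkeletonSequence":
        if c <= 0:
            raise ValueError("scale must be positive")
        return SkeletonSequence(self.timestamps * c, self.positions,
                                validate_rate=False)


@dataclass(frozen=True)
class TaskRecording:
    """One execution of one motor task: id, repetition index, cues, kinematics."""

    task: str
    repetition: int
    cue_times: tuple[float, ...]
    sequence: SkeletonSequence

    def __post_init__(self):
        if self.task not in TASKS:
            raise SkeletonFormatError(f"unknown task {self.task!r}")
        if self.repetition < 1:
            raise SkeletonFormatError("repetition index is 1-based")
        cues = tuple(float(c) for c in self.cue_times)
        object.__setattr__(self, "cue_times", cues)
        expected = TASK_CUE_COUNTS[self.task]
        if len(cues) != expected:
            raise SkeletonFormatError(
                f"{self.task} requires {expected} cue{'s' if expected != 1 else ''}, "
                f"got {len(cues)}"
            )
        if list(cues) != sorted(cues):
            raise SkeletonFormatError("cue_times not sorted")
        t0, t1 = self.sequence.timestamps[0], self.sequence.timestamps[-1]
        for c in cues:
            if not (t0 <= c <= t1):
                raise SkeletonFormatError(
                    f"cue at {c:.3f} s outside recording span [{t0:.3f}, {t1:.3f}]"
                )


# --------------------------------------------------------------------------
# Subjects
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SubjectRecord:
    """Demographics and stature of one participant; BMI is derived."""

    subject_id: str
    cohort: str
    sex: str
    age: float
    height_cm: float
    weight_kg: float

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise SkeletonFormatError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for label, value, lo, hi in (
            ("age", self.age, 10, 100),
            ("height_cm", self.height_cm, 100, 250),
            ("weight_kg", self.weight_kg, 30, 200),
        ):
            v = float(value)
            if not (lo < v < hi):
                raise SkeletonFormatError(
                    f"{label}={v} outside plausible range ({lo}, {hi}) "
                    f"for subject {self.subject_id!r}"
                )

    @property
    def bmi(self) -> float:
        """Body mass index, kg/m^2."""
        return self.weight_kg / (self.height_cm / 100.0) ** 2


# --------------------------------------------------------------------------
# Parameter vocabulary
# --------------------------------------------------------------------------

#: (name, unit, task) for the 23 spatiotemporal parameters, in report order.
PARAMETER_DEFS: tuple[tuple[str, str, str], ...] = (
    ("poco_deflection_range_open", "deg", "POCO"),
    ("poco_sway_speed_open", "deg/s", "POCO"),
    ("poco_deflection_range_closed", "deg", "POCO"),
    ("poco_sway_speed_closed", "deg/s", "POCO"),
    ("poco_romberg_range", "ratio", "POCO"),
    ("poco_romberg_speed", "ratio", "POCO"),
    ("scsw_gait_speed", "m/s", "SCSW"),
    ("scsw_step_length", "cm", "SCSW"),
    ("scsw_cadence", "steps/min", "SCSW"),
    ("smsw_gait_speed", "m/s", "SMSW"),
    ("slw_progression_speed", "m/s", "SLW"),
    ("slw_trunk_sway_variability", "deg", "SLW"),
    ("slw_arm_movement_variability", "deg", "SLW"),
    ("sas_stand_up_time", "s", "SAS"),
    ("sas_stand_up_trunk_deflection", "cm", "SAS"),
    ("sas_stand_up_hand_deflection", "cm", "SAS"),
    ("sas_sitting_down_time", "s", "SAS"),
    ("sas_sitting_down_trunk_deflection", "cm", "SAS"),
    ("sas_sitting_down_hand_deflection", "cm", "SAS"),
    ("sip_cadence", "steps/min", "SIP"),
    ("sip_knee_amplitude", "cm", "SIP"),
    ("sip_amplitude_asymmetry", "%", "SIP"),
    ("sip_arrhythmicity", "%", "SIP"),
)

PARAMETER_NAMES: tuple[str, ...] = tuple(d[0] for d in PARAMETER_DEFS)
PARAMETER_UNITS: Mapping[str, str] = {d[0]: d[1] for d in PARAMETER_DEFS}
PARAMETER_TASKS: Mapping[str, str] = {d[0]: d[2] for d in PARAMETER_DEFS}
TASK_PARAMETERS: Mapping[str, tuple[str, ...]] = {
    task: tuple(n for n, _, t in PARAMETER_DEFS if t == task) for task in TASKS
}

#: Parameters bounded in [0, 200] % by definition.
_PERCENT_PARAMS = ("sip_amplitude_asymmetry", "sip_arrhythmicity")


class ParameterVector:
    """The 23 named spatiotemporal parameters of one subject.

    Every parameter is either a finite non-negative value or flagged missing
    with a reason (e.g. a Romberg ratio whose eyes-open denominator is zero,
    or a task that was not recorded).
    """

    def __init__(self):
        self._values: dict[str, float | None] = {n: None for n in PARAMETER_NAMES}
        self._flags: dict[str, str | None] = {n: "not computed" for n in PARAMETER_NAMES}

    def set(self, name: str, value: float) -> None:
        if name not in self._values:
            raise KeyError(f"unknown parameter {name!r}")
        v = float(value)
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if name in _PERCENT_PARAMS and v > 200:
            raise ValueError(f"{name}={v} outside [0, 200] %")
        self._values[name] = v
        self._flags[name] = None

    def flag_missing(self, name: str, reason: str) -> None:
        if name not in self._values:
            raise KeyError(f"unknown parameter {name!r}")
        self._values[name] = None
        self._flags[name] = reason

    def __getitem__(self, name: str) -> float | None:
        if name not in self._values:
            raise KeyError(f"unknown parameter {name!r}")
        return self._values[name]

    def flag(self, name: str) -> str | None:
        return self._flags[name]

    def is_missing(self, name: str) -> bool:
        return self._values[name] is None

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(n for n in PARAMETER_NAMES if self._values[n] is None)

    def as_series(self) -> pd.Series:
        """Values in report order; missing entries are NaN."""
        return pd.Series(
            [np.nan if self._values[n] is None else self._values[n]
             for n in PARAMETER_NAMES],
            index=list(PARAMETER_NAMES), dtype=float,
        )

    def as_frame(self, subject_id: str) -> pd.DataFrame:
        """Tidy rows ``subject_id,parameter,value,unit,flag``."""
        return pd.DataFrame({
            "subject_id": subject_id,
            "parameter": list(PARAMETER_NAMES),
            "value": [self._values[n] for n in PARAMETER_NAMES],
            "unit": [PARAMETER_UNITS[n] for n in PARAMETER_NAMES],
            "flag": [self._flags[n] or "" for n in PARAMETER_NAMES],
        })

    @classmethod
    def from_mapping(cls, values: Mapping[str, float | None],
                     flags: Mapping[str, str] | None = None) -> "ParameterVector":
        pv = cls()
        flags = flags or {}
        for name in PARAMETER_NAMES:
            v = values.get(name)
            if v is None or (isinstance(v, float) and not math.isfinite(v)):
                pv.flag_missing(name, flags.get(name, "missing"))
            else:
                pv.set(name, v)
        return pv


# --------------------------------------------------------------------------
# Skeleton CSV dialect
# --------------------------------------------------------------------------
#
# Line 1:  # task=<ID> repetition=<k> cues=<t1;t2;...>   (cues= may be empty)
# Line 2:  time_s,<landmark>_x,<landmark>_y,<landmark>_z  x 25 landmarks
# Body:    one frame per line, decimal point, UTF-8, newline-terminated.

_POSITION_COLUMNS = tuple(
    f"{name}_{axis}" for name in LANDMARKS for axis in ("x", "y", "z")
)
_HEADER_COLUMNS = ("time_s",) + _POSITION_COLUMNS


def write_skeleton_csv(rec: TaskRecording, path: str | os.PathLike) -> None:
    """Write a recording in the skeleton CSV dialect (lossless to 1e-6 m/s)."""
    seq = rec.sequence
    cues = ";".join(f"{c:.6f}" for c in rec.cue_times)
    buf = io.StringIO()
    buf.write(f"# task={rec.task} repetition={rec.repetition} cues={cues}\n")
    buf.write(",".join(_HEADER_COLUMNS) + "\n")
    flat = seq.positions.reshape(seq.n_frames, -1)
    for t, row in zip(seq.timestamps, flat):
        buf.write(f"{t:.6f}," + ",".join(f"{v:.6f}" for v in row) + "\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


def read_skeleton_csv(path: str | os.PathLike) -> TaskRecording:
    """Parse one recording; every container invariant is enforced on ingest."""
    with open(path, "r", encoding="utf-8") as fh:
        meta_line = fh.readline().strip()
        if not meta_line.startswith("# "):
            raise SkeletonFormatError(f"{path}: line 1: missing '# task=...' header")
        meta: dict[str, str] = {}
        for tok in meta_line[2:].split():
            if "=" not in tok:
                raise SkeletonFormatError(f"{path}: line 1: bad token {tok!r}")
            k, v = tok.split("=", 1)
            meta[k] = v
        for key in ("task", "repetition", "cues"):
            if key not in meta:
                raise SkeletonFormatError(f"{path}: line 1: missing field {key!r}")
        header = fh.readline().strip()
        cols = tuple(header.split(","))
        if cols != _HEADER_COLUMNS:
            missing = set(_HEADER_COLUMNS) - set(cols)
            detail = f"missing column(s) {sorted(missing)[:3]}" if missing \
                else "column order mismatch"
            raise SkeletonFormatError(f"{path}: line 2: {detail}")
        try:
            body = pd.read_csv(fh, header=None, names=_HEADER_COLUMNS, dtype=float)
        except ValueError as exc:
            raise SkeletonFormatError(f"{path}: non-numeric value in body: {exc}") from exc
    if body.shape[0] < 2:
        raise SkeletonFormatError(f"{path}: no frames")
    ts = body["time_s"].to_numpy()
    pos = body[list(_POSITION_COLUMNS)].to_numpy().reshape(-1, len(LANDMARKS), 3)
    cues = tuple(float(c) for c in meta["cues"].split(";") if c != "")
    try:
        seq = SkeletonSequence(ts, pos)
        return TaskRecording(
            task=meta["task"],
            repetition=int(meta["repetition"]),
            cue_times=cues,
            sequence=seq,
        )
    except SkeletonFormatError as exc:
        raise SkeletonFormatError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# Subjects CSV
# --------------------------------------------------------------------------

_SUBJECT_COLUMNS = ("id", "cohort", "sex", "age", "height_cm", "weight_kg")


def read_subjects_csv(path: str | os.PathLike) -> list[SubjectRecord]:
    """Read the subjects metadata table ``id,cohort,sex,age,height_cm,weight_kg``."""
    df = pd.read_csv(path, dtype={"id": str, "cohort": str, "sex": str})
    if tuple(df.columns) != _SUBJECT_COLUMNS:
        raise SkeletonFormatError(
            f"{path}: expected header {','.join(_SUBJECT_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    records = []
    for i, row in df.iterrows():
        try:
            age = float(row["age"])
            height = float(row["height_cm"])
            weight = float(row["weight_kg"])
        except (TypeError, ValueError) as exc:
            raise SkeletonFormatError(f"{path}: row {i + 1}: non-numeric stature") from exc
        try:
            records.append(SubjectRecord(
                subject_id=str(row["id"]), cohort=str(row["cohort"]),
                sex=str(row["sex"]), age=age, height_cm=height, weight_kg=weight,
            ))
        except SkeletonFormatError as exc:
            raise SkeletonFormatError(f"{path}: row {i + 1}: {exc}") from exc
    return records


def write_subjects_csv(records: Iterable[SubjectRecord],
                       path: str | os.PathLike) -> None:
    df = pd.DataFrame([{
        "id": r.subject_id, "cohort": r.cohort, "sex": r.sex,
        "age": r.age, "height_cm": r.height_cm, "weight_kg": r.weight_kg,
    } for r in records], columns=list(_SUBJECT_COLUMNS))
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# Tidy parameter tables
# --------------------------------------------------------------------------

def parameter_table_to_tidy(table: pd.DataFrame) -> pd.DataFrame:
    """Wide (subjects x 23 parameters) -> tidy ``subject_id,parameter,value,unit,flag``."""
    rows = []
    for sid, row in table.iterrows():
        for name in PARAMETER_NAMES:
            v = row.get(name, np.nan)
            rows.append({
                "subject_id": sid, "parameter": name,
                "value": v, "unit": PARAMETER_UNITS[name],
                "flag": "" if pd.notna(v) else "missing",
            })
    return pd.DataFrame(rows)


def tidy_to_parameter_table(tidy: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`parameter_table_to_tidy` (wide table indexed by subject)."""
    wide = tidy.pivot(index="subject_id", columns="parameter", values="value")
    return wide.reindex(columns=list(PARAMETER_NAMES))
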