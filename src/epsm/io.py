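"""Shared data model and CSV input/output.

Recordings are long-format labelled 6-axis IMU streams (timestamp, tri-axial
accelerometer, tri-axial gyroscope, activity label) tagged with a user id and
a sensor location.  Because public activity-recognition corpora use wildly
different column names, the reader takes a *schema*: a mapping from the
canonical field names to the column names actually present in the file.

Evaluation results are exchanged as a long-format CSV with one row per
(dataset, sensor, user, algorithm, approach, performance type), deliberately
shaped for downstream mixed-model analysis in external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

#: canonical recording fields the schema must cover
RECORDING_FIELDS = (
    "timestamp",
    "accel_x", "accel_y", "accel_z",
    "gyro_x", "gyro_y", "gyro_z",
    "label",
    "user",
    "sensor",
)

#: identity schema: file columns already use the canonical names
DEFAULT_SCHEMA: dict[str, str] = {name: name for name in RECORDING_FIELDS}

APPROACHES = ("PIM", "PSM", "EPSM", "WEPSM", "WEPSMbf")
PERFORMANCE_TYPES = ("subject_dependent", "subject_independent")

RESULT_COLUMNS = (
    "dataset", "sensor", "user", "algorithm", "approach",
    "performance_type", "kappa", "accuracy", "error_rate", "weighted_f",
)


@dataclass
class RawRecording:
    """One user/sensor's timestamped, labelled 6-axis IMU stream.

    All per-sample sequences have equal length; ``nominal_fs`` is the
    sampling rate the device was configured for (actual inter-arrival times
    may deviate, e.g. across trial gaps).
    """

    user_id: str
    sensor_location: str
    nominal_fs: float
    timestamps: np.ndarray          # (n,) seconds
    accel: np.ndarray               # (n, 3) device units
    gyro: np.ndarray                # (n, 3) device units
    labels: np.ndarray              # (n,) activity identifiers

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.timestamps)
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValueError(
                f"recording {self.user_id}/{self.sensor_location}: sequences "
                f"have unequal lengths (timestamps {n}, accel "
                f"{self.accel.shape}, gyro {self.gyro.shape})"
            )
        if len(self.labels) != n:
            raise ValueError(
                f"recording {self.user_id}/{self.sensor_location}: "
                f"{len(self.labels)} labels for {n} samples"
            )
        if not self.nominal_fs > 0:
            raise ValueError(f"nominal_fs must be > 0, got {self.nominal_fs}")
        if np.isnan(self.timestamps).any() or np.isnan(self.accel).any() \
                or np.isnan(self.gyro).any():
            raise ValueError(
                f"recording {self.user_id}/{self.sensor_location} contains "
                "missing sensor values"
            )

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class EvaluationResult:
    """One performance measurement: a user × algorithm × approach cell."""

    dataset: str
    sensor: str
    user: str
    algorithm: str
    approach: str
    performance_type: str
    kappa: float
    accuracy: float
    error_rate: float
    weighted_f: float

    def __post_init__(self) -> None:
        if self.approach not in APPROACHES:
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.performance_type not in PERFORMANCE_TYPES:
            raise ValueError(
                f"unknown performance type {self.performance_type!r}")
        if abs(self.error_rate - (1.0 - self.accuracy)) > 1e-12:
            raise ValueError("error_rate must equal 1 - accuracy")


def read_recordings(
    path,
    schema: Mapping[str, str] | None = None,
    nominal_fs: float = 50.0,
) -> list[RawRecording]:
    """Read a long-format recordings CSV into one RawRecording per
    (user, sensor) group.  Rows are kept in file order within a group.

    Raises :class:`SchemaError` if a declared column is missing and
    :class:`ParseError` (naming the first offending row) if a sensor value
    is non-numeric or missing.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    missing = [f for f in RECORDING_FIELDS if f not in schema]
    if missing:
        raise SchemaError(f"schema does not map canonical fields: {missing}")

    frame = pd.read_csv(path, dtype={schema["user"]: str,
                                     schema["sensor"]: str,
                                     schema["label"]: str})
    absent = [schema[f] for f in RECORDING_FIELDS
              if schema[f] not in frame.columns]
    if absent:
        raise SchemaError(f"{path}: missing column(s) {absent}")

    numeric_fields = ("timestamp", "accel_x", "accel_y", "accel_z",
                      "gyro_x", "gyro_y", "gyro_z")
    numeric = {}
    for f in numeric_fields:
        col = pd.to_numeric(frame[schema[f]], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raise ParseError(
                f"{path}: non-numeric or missing value in column "
                f"{schema[f]!r} at row {int(bad[0])}"
            )
        numeric[f] = col.to_numpy(dtype=float)

    recordings = []
    keys = pd.Series(
        list(zip(frame[schema["user"]], frame[schema["sensor"]])))
    for (user, sensor), idx in keys.groupby(keys, sort=False).groups.items():
        idx = np.asarray(idx)
        recordings.append(RawRecording(
            user_id=str(user),
            sensor_location=str(sensor),
            nominal_fs=nominal_fs,
            timestamps=numeric["timestamp"][idx],
            accel=np.column_stack(
                [numeric["accel_" + a][idx] for a in "xyz"]),
            gyro=np.column_stack(
                [numeric["gyro_" + a][idx] for a in "xyz"]),
            labels=frame[schema["label"]].to_numpy(dtype=object)[idx],
        ))
    return recordings


def write_recording(recording: RawRecording, path) -> None:
    """Write one recording in the canonical long-format CSV layout."""
    pd.DataFrame({
        "timestamp": recording.timestamps,
        "accel_x": recording.accel[:, 0],
        "accel_y": recording.accel[:, 1],
        "accel_z": recording.accel[:, 2],
        "gyro_x": recording.gyro[:, 0],
        "gyro_y": recording.gyro[:, 1],
        "gyro_z": recording.gyro[:, 2],
        "label": recording.labels,
        "user": recording.user_id,
        "sensor": recording.sensor_location,
    }).to_csv(path, index=False)


def write_recordings(recordings: Sequence[RawRecording], path) -> None:
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "timestamp": rec.timestamps,
            "accel_x": rec.accel[:, 0], "accel_y": rec.accel[:, 1],
            "accel_z": rec.accel[:, 2],
            "gyro_x": rec.gyro[:, 0], "gyro_y": rec.gyro[:, 1],
            "gyro_z": rec.gyro[:, 2],
            "label": rec.labels, "user": rec.user_id,
            "sensor": rec.sensor_location,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def results_to_frame(results: Iterable[EvaluationResult]) -> pd.DataFrame:
    rows = [{f.name: getattr(r, f.name) for f in fields(EvaluationResult)}
            for r in results]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Sequence[EvaluationResult], path) -> None:
    """Write evaluation results as long-format CSV with a stable column
    order; an empty sequence yields a header-only file."""
    results_to_frame(results).to_csv(path, index=False)


def read_results(path) -> list[EvaluationResult]:
    frame = pd.read_csv(
        path, dtype={c: str for c in RESULT_COLUMNS[:6]})
    if frame.empty:
        return []
    return [
        EvaluationResult(
            dataset=row.dataset, sensor=row.sensor, user=row.user,
            algorithm=row.algorithm, approach=row.approach,
            performance_type=row.performance_type,
            kappa=float(row.kappa), accuracy=float(row.accuracy),
            error_rate=float(row.error_rate),
            weighted_f=float(row.weighted_f),
        )
        for row in frame.itertuples(index=False)
    ]
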