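"""Timestamp repair, natural-trial splitting, 15 s batching, and
gravity/body separation.

A *trial* is a contiguous single-activity segment of a recording.  Trials are
the atomic grouping unit of the cross-validation protocols: windows derived
from one trial never end up on both sides of a train/test split.  The
accelerometer signal of each trial is decomposed into a low-frequency
*gravity* component (posture) and the residual *body* component (motion) by
a zero-phase elliptic IIR low-pass filter, so each trial carries three
tri-axial signals: gyroscope, body acceleration, gravity acceleration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, PreprocessingError
from .io import RawRecording

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 1.5       # s; split when inter-arrival time exceeds this
DEFAULT_BATCH_LEN = 15.0    # s; natural trials are cut into batches this long
DEFAULT_WINDOW_LEN = 3.0    # s; a batch remainder shorter than this is useless


@dataclass(frozen=True)
class FilterSpec:
    """Elliptic IIR low-pass used to isolate the gravity component.

    The defaults (order 3, 0.3 Hz cutoff, 0.01 dB passband ripple, 60 dB
    stopband attenuation, applied forward-backward for zero phase) are
    conventional for gravity separation; all are configurable.
    """

    order: int = 3
    cutoff: float = 0.3             # Hz
    passband_ripple: float = 0.01   # dB
    stopband_attenuation: float = 60.0  # dB

    def design(self, fs: float) -> np.ndarray:
        """Second-order sections of the filter designed for rate ``fs``."""
        if not 0 < self.cutoff < fs / 2:
            raise ConfigurationError(
                f"cutoff {self.cutoff} Hz not in (0, fs/2) for fs={fs}")
        return signal.ellip(
            self.order, self.passband_ripple, self.stopband_attenuation,
            self.cutoff, btype="lowpass", fs=fs, output="sos")


@dataclass
class Segment:
    """A trial precursor: one contiguous single-activity raw segment."""

    trial_id: str
    user_id: str
    sensor_location: str
    label: str
    fs: float
    timestamps: np.ndarray
    accel: np.ndarray   # (n, 3)
    gyro: np.ndarray    # (n, 3)

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return len(self) / self.fs


@dataclass
class Trial:
    """A preprocessed trial: gyroscope plus separated acceleration signals.

    ``body_accel + gravity_accel`` reconstructs the original accelerometer
    signal exactly, by construction.
    """

    trial_id: str
    user_id: str
    sensor_location: str
    label: str
    fs: float
    gyro: np.ndarray            # (n, 3)
    body_accel: np.ndarray      # (n, 3)
    gravity_accel: np.ndarray   # (n, 3)

    def __post_init__(self) -> None:
        n = len(self.gyro)
        if not (len(self.body_accel) == len(self.gravity_accel) == n):
            raise ValueError(f"trial {self.trial_id}: unequal signal lengths")

    def __len__(self) -> int:
        return len(self.gyro)

    @property
    def duration(self) -> float:
        return len(self) / self.fs


def repair_timestamps(recording: RawRecording) -> RawRecording:
    """Regenerate timestamps at the nominal rate when they are corrupt.

    Some corpora store a constant timestamp per trial (a spreadsheet
    export artefact).  When more than half of the inter-arrival times are
    non-positive, timestamps are replaced by ``t0 + i / nominal_fs``;
    otherwise the recording is returned unchanged.
    """
    if not recording.nominal_fs > 0:
        raise ConfigurationError(
            f"nominal_fs must be > 0, got {recording.nominal_fs}")
    if len(recording) < 2:
        return recording
    dts = np.diff(recording.timestamps)
    if np.mean(dts <= 0) <= 0.5:
        return recording
    log.warning(
        "recording %s/%s: %.0f%% of inter-arrival times are non-positive; "
        "regenerating timestamps at %.6g Hz",
        recording.user_id, recording.sensor_location,
        100 * np.mean(dts <= 0), recording.nominal_fs)
    t0 = recording.timestamps[0]
    new_ts = t0 + np.arange(len(recording)) / recording.nominal_fs
    return RawRecording(
        user_id=recording.user_id,
        sensor_location=recording.sensor_location,
        nominal_fs=recording.nominal_fs,
        timestamps=new_ts,
        accel=recording.accel,
        gyro=recording.gyro,
        labels=recording.labels,
    )


def split_natural_trials(
    recording: RawRecording, max_gap: float = DEFAULT_MAX_GAP
) -> list[Segment]:
    """Split a recording into maximal single-activity segments.

    A new trial starts whenever the activity label changes or the
    inter-arrival time strictly exceeds ``max_gap`` seconds.  Every sample
    belongs to exactly one trial and order is preserved.
    """
    n = len(recording)
    if n == 0:
        return []
    labels = recording.labels
    ts = recording.timestamps
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        breaks[1:] = (labels[1:] != labels[:-1]) | (np.diff(ts) > max_gap)
    starts = np.flatnonzero(breaks)
    bounds = np.append(starts, n)
    segments = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        segments.append(Segment(
            trial_id=f"{recording.user_id}|{recording.sensor_location}|t{i}",
            user_id=recording.user_id,
            sensor_location=recording.sensor_location,
            label=str(labels[a]),
            fs=recording.nominal_fs,
            timestamps=ts[a:b],
            accel=recording.accel[a:b],
            gyro=recording.gyro[a:b],
        ))
    return segments


def batch_trial(
    segment: Segment,
    batch_len: float = DEFAULT_BATCH_LEN,
    min_len: float = DEFAULT_WINDOW_LEN,
) -> list[Segment]:
    """Cut a natural trial into consecutive non-overlapping batches.

    Batching guarantees multiple trials per user and activity, which the
    leave-trials-out protocol needs.  A trailing remainder is kept iff it is
    at least ``min_len`` seconds (the window length) — a shorter batch could
    not yield a single analysis window.
    """
    if not batch_len > 0:
        raise ConfigurationError(f"batch_len must be > 0, got {batch_len}")
    n = len(segment)
    batch_n = int(round(batch_len * segment.fs))
    min_n = int(round(min_len * segment.fs))
    batches = []
    j = 0
    for start in range(0, n, batch_n):
        stop = min(start + batch_n, n)
        if stop - start < batch_n and stop - start < min_n:
            break   # trailing remainder too short to window
        batches.append(Segment(
            trial_id=f"{segment.trial_id}|b{j}",
            user_id=segment.user_id,
            sensor_location=segment.sensor_location,
            label=segment.label,
            fs=segment.fs,
            timestamps=segment.timestamps[start:stop],
            accel=segment.accel[start:stop],
            gyro=segment.gyro[start:stop],
        ))
        j += 1
    return batches


def separate_gravity_body(
    accel: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Split an accelerometer signal into (gravity, body) components.

    Gravity is the zero-phase elliptic low-pass of each axis; body is the
    exact residual ``accel - gravity``, so the decomposition is additive to
    machine precision.
    """
    accel = np.asarray(accel, dtype=float)
    sos = spec.design(fs)
    try:
        gravity = signal.sosfiltfilt(sos, accel, axis=0)
    except ValueError as exc:
        raise PreprocessingError(
            f"signal of length {len(accel)} too short for zero-phase "
            f"filtering with an order-{spec.order} elliptic filter: {exc}"
        ) from exc
    body = accel - gravity
    return gravity, body


def preprocess_segment(
    segment: Segment, filter_spec: FilterSpec = FilterSpec()
) -> Trial:
    """Separate a segment's accelerometer signal, yielding a full Trial."""
    try:
        gravity, body = separate_gravity_body(
            segment.accel, segment.fs, filter_spec)
    except PreprocessingError as exc:
        raise PreprocessingError(
            f"trial {segment.trial_id}: {exc}") from exc
    return Trial(
        trial_id=segment.trial_id,
        user_id=segment.user_id,
        sensor_location=segment.sensor_location,
        label=segment.label,
        fs=segment.fs,
        gyro=segment.gyro,
        body_accel=body,
        gravity_accel=gravity,
    )


def preprocess_recording(
    recording: RawRecording,
    max_gap: float = DEFAULT_MAX_GAP,
    batch_len: float = DEFAULT_BATCH_LEN,
    window_len: float = DEFAULT_WINDOW_LEN,
    filter_spec: FilterSpec = FilterSpec(),
) -> list[Trial]:
    """Full preprocessing pipeline for one recording.

    Repairs timestamps, splits into natural trials, batches each trial to
    ``batch_len`` seconds, and separates gravity/body acceleration.  Batches
    shorter than one window are dropped.
    """
    recording = repair_timestamps(recording)
    trials = []
    for segment in split_natural_trials(recording, max_gap=max_gap):
        for batch in batch_trial(segment, batch_len=batch_len,
                                 min_len=window_len):
            if batch.duration < window_len:
                continue
            trials.append(preprocess_segment(batch, filter_spec))
    return trials
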