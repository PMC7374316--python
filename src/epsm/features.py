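"""Sliding-window segmentation and the per-window feature inventory.

Windows are 3 s long with 50% overlap by default and never cross a trial
boundary.  From every window we extract, in a fixed canonical order:

* per axis of the gyroscope, body-acceleration and gravity-acceleration
  signals: mean, standard deviation, skewness (Fisher) and excess kurtosis
  (9 axes x 4 = 36 features);
* per axis of the gyroscope and body-acceleration signals: normalised
  spectral power entropy and peak-power frequency (6 axes x 2 = 12);
* per gyroscope / body-acceleration signal: the signal magnitude area,
  i.e. the per-sample mean of |x|+|y|+|z| (2);
* per gyroscope / body-acceleration signal: the three pairwise Pearson
  correlations between its axes (6).

That is 56 features per window.  Gravity acceleration contributes only its
moments: being a near-DC posture signal, its spectrum and axis couplings
carry no extra information.

Spectral estimates use the one-sided periodogram of the raw (non-detrended)
window with the DC bin excluded; entropy is normalised by log(#bins) so it
lies in [0, 1].  Degenerate windows (zero variance, zero power) map skew,
kurtosis, correlations, entropy and peak frequency to 0 rather than NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .errors import EpsmError
from .preprocessing import Trial

DEFAULT_WINDOW_LEN = 3.0   # s
DEFAULT_OVERLAP = 0.5      # fraction of the window shared by neighbours

#: metadata columns of a feature matrix; everything else is a feature
METADATA_COLUMNS = ("user", "trial", "label")

_SIGNALS = ("gyro", "body", "gravity")
_SPECTRAL_SIGNALS = ("gyro", "body")
_AXES = ("x", "y", "z")
_MOMENTS = ("mean", "sd", "skew", "kurtosis")
_AXIS_PAIRS = (("x", "y"), ("x", "z"), ("y", "z"))


@dataclass
class Window:
    """A fixed-length slice of one trial's three tri-axial signals."""

    trial_id: str
    user_id: str
    label: str
    start: float            # seconds within the trial
    fs: float
    gyro: np.ndarray        # (w, 3)
    body: np.ndarray        # (w, 3)
    gravity: np.ndarray     # (w, 3)


def feature_names() -> list[str]:
    """The canonical feature-name order, identical for every window."""
    names = [f"{sig}_{ax}_{m}"
             for sig in _SIGNALS for ax in _AXES for m in _MOMENTS]
    names += [f"{sig}_{ax}_{feat}"
              for sig in _SPECTRAL_SIGNALS for ax in _AXES
              for feat in ("spectral_entropy", "peak_freq")]
    names += [f"{sig}_sma" for sig in _SPECTRAL_SIGNALS]
    names += [f"{sig}_corr_{a}{b}"
              for sig in _SPECTRAL_SIGNALS for a, b in _AXIS_PAIRS]
    return names


FEATURE_NAMES = tuple(feature_names())


def slide_windows(
    trial: Trial,
    window_len: float = DEFAULT_WINDOW_LEN,
    overlap: float = DEFAULT_OVERLAP,
) -> list[Window]:
    """Cut a trial into overlapping fixed-length windows.

    Windows start at 0 and advance by ``window_len * (1 - overlap)``;
    trailing partial windows are dropped, so a trial shorter than one
    window yields an empty list.  The count obeys
    ``floor((L - w) / step) + 1`` for trial length L >= w.
    """
    if not 0 <= overlap < 1:
        raise EpsmError(f"overlap must be in [0, 1), got {overlap}")
    w = int(round(window_len * trial.fs))
    step_f = window_len * (1 - overlap) * trial.fs  # samples, may be fractional
    if step_f < 1:
        raise EpsmError("window step is below one sample")
    n = len(trial)
    if n < w:
        return []
    count = int(np.floor((n - w) / step_f + 1e-9)) + 1
    windows = []
    for k in range(count):
        start = int(round(k * step_f))
        windows.append(Window(
            trial_id=trial.trial_id,
            user_id=trial.user_id,
            label=trial.label,
            start=start / trial.fs,
            fs=trial.fs,
            gyro=trial.gyro[start:start + w],
            body=trial.body_accel[start:start + w],
            gravity=trial.gravity_accel[start:start + w],
        ))
    return windows


def _nan_to_zero(x: np.ndarray) -> np.ndarray:
    return np.where(np.isfinite(x), x, 0.0)


def _moments(sig: np.ndarray) -> np.ndarray:
    """mean, sd, Fisher skew, excess kurtosis per axis; degenerate -> 0."""
    mean = sig.mean(axis=0)
    sd = sig.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        # constant windows trip scipy's precision-loss warning; their
        # skew/kurtosis is deliberately mapped to 0 below
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = _nan_to_zero(np.asarray(sp_stats.skew(sig, axis=0)))
        kurt = _nan_to_zero(np.asarray(sp_stats.kurtosis(sig, axis=0)))
    return np.column_stack([mean, sd, skew, kurt])  # (3 axes, 4)


def _spectral(sig: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Normalised spectral power entropy and peak-power frequency per axis.

    One-sided periodogram of the raw window, DC bin excluded.  Zero-power
    axes map both features to 0.
    """
    freqs, psd = sp_signal.periodogram(sig, fs=fs, axis=0, detrend=False)
    freqs, psd = freqs[1:], psd[1:]     # drop DC
    total = psd.sum(axis=0)
    # leakage floor: a constant signal has only round-off power off DC
    floor = 1e-18 * len(sig) * np.mean(sig ** 2, axis=0)
    nbins = len(freqs)
    entropy = np.zeros(sig.shape[1])
    peak = np.zeros(sig.shape[1])
    for a in range(sig.shape[1]):
        if total[a] <= floor[a] or total[a] <= 0 or nbins < 2:
            continue
        p = psd[:, a] / total[a]
        nz = p > 0
        entropy[a] = -(p[nz] * np.log(p[nz])).sum() / np.log(nbins)
        peak[a] = freqs[np.argmax(psd[:, a])]
    return entropy, peak


def _correlations(sig: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations (xy, xz, yz); constant axes -> 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(sig, rowvar=False)
    return _nan_to_zero(np.array([c[0, 1], c[0, 2], c[1, 2]]))


def extract_features(window: Window) -> np.ndarray:
    """The 56-value feature vector of one window, in canonical order."""
    signals = {"gyro": window.gyro, "body": window.body,
               "gravity": window.gravity}
    parts = [_moments(signals[s]).ravel() for s in _SIGNALS]
    for s in _SPECTRAL_SIGNALS:
        entropy, peak = _spectral(signals[s], window.fs)
        parts.append(np.column_stack([entropy, peak]).ravel())
    parts.append(np.array([np.abs(signals[s]).sum(axis=1).mean()
                           for s in _SPECTRAL_SIGNALS]))
    parts.extend(_correlations(signals[s]) for s in _SPECTRAL_SIGNALS)
    return np.concatenate(parts)


def extract_feature_matrix(
    trials: Iterable[Trial],
    window_len: float = DEFAULT_WINDOW_LEN,
    overlap: float = DEFAULT_OVERLAP,
) -> pd.DataFrame:
    """Window all trials and extract features into one long DataFrame.

    Columns: the metadata columns (user, trial, label) followed by the
    canonical feature names; one row per window.
    """
    meta: list[tuple] = []
    rows: list[np.ndarray] = []
    for trial in trials:
        for win in slide_windows(trial, window_len, overlap):
            meta.append((win.user_id, win.trial_id, win.label))
            rows.append(extract_features(win))
    matrix = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES))),
        columns=list(FEATURE_NAMES))
    meta_frame = pd.DataFrame(meta, columns=list(METADATA_COLUMNS))
    return pd.concat([meta_frame, matrix], axis=1)


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in METADATA_COLUMNS]


class Standardizer:
    """Per-feature (x - mean) / sd transform fitted on training rows.

    Uses the population standard deviation; features that are constant in
    the training data get s := 1 so they map to 0 and stay well-posed
    downstream.
    """

    def __init__(self) -> None:
        self.mean_: pd.Series | None = None
        self.scale_: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Standardizer":
        cols = feature_columns(train)
        if train.empty or not cols:
            raise EpsmError("cannot fit a standardizer on an empty matrix")
        self.mean_ = train[cols].mean()
        scale = train[cols].std(ddof=0)
        self.scale_ = scale.mask(scale == 0, 1.0)
        return self

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        if self.mean_ is None:
            raise EpsmError("standardizer used before fitting")
        out = matrix.copy()
        cols = self.mean_.index
        out[cols] = (matrix[cols] - self.mean_) / self.scale_
        return out


def standardize_features(
    train: pd.DataFrame, *others: pd.DataFrame
) -> tuple:
    """Standardise the training matrix and any further matrices with the
    training-fitted parameters.  Returns the transformed matrices followed
    by the fitted :class:`Standardizer`."""
    scaler = Standardizer().fit(train)
    transformed = [scaler.transform(train)]
    transformed.extend(scaler.transform(m) for m in others)
    return (*transformed, scaler)
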