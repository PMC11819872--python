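"""Feature engineering: smoothing, spectral features, augmentation.

Builds the 17-column feature table consumed by the state classifiers:
four noisy channels, their trailing rolling means, the dominant frequency
of each channel over a trailing window, and five contextual/demographic
columns, plus the binary ``state`` target attached from the
context-adaptive labeler.

Time-shift augmentation displaces each subject's feature sequences by a
few samples while keeping the label at the original alignment, teaching
classifiers tolerance to sensor-clock misalignment.  Augmented rows carry
a provenance flag and must never enter an evaluation split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ValidationError, VitalsSeries
from .labeling import label_series

__all__ = [
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "rolling_mean",
    "dominant_frequency",
    "build_feature_table",
    "time_shift_augment",
]

_CHANNEL_NAMES = {"hr": "HR", "spo2": "SpO2", "resp": "RESP", "pulse": "Pulse"}

#: The 17 model-input columns, in canonical order.
FEATURE_COLUMNS = [
    "HR_noisy", "SpO2_noisy", "RESP_noisy", "Pulse_noisy",
    "HR_smooth", "SpO2_smooth", "RESP_smooth", "Pulse_smooth",
    "HR_fft", "SpO2_fft", "RESP_fft", "Pulse_fft",
    "Age", "Gender", "Altitude", "Temperature", "Activity_level",
]

#: Serialized table schema: bookkeeping + features + target.
TABLE_COLUMNS = ["subject_id", "t"] + FEATURE_COLUMNS + ["state"]

#: Signal-derived columns displaced by time-shift augmentation.
SIGNAL_COLUMNS = FEATURE_COLUMNS[:12]

MIN_FFT_HISTORY = 8


def rolling_mean(series, window: int) -> np.ndarray:
    """Trailing mean over ``min(window, i + 1)`` samples.

    Partial windows at the head use the samples available so far, so the
    output has the input's length and a constant series is a fixed point.
    """
    if window < 1:
        raise ValidationError(f"window must be >= 1, got {window}")
    x = pd.Series(np.asarray(series, dtype=float))
    return x.rolling(window, min_periods=1).mean().to_numpy()


def dominant_frequency(window, sample_rate: float = 1.0) -> float:
    """Frequency (Hz) of the strongest non-DC DFT bin of a window.

    The window mean is removed before the transform so the DC bin never
    dominates; ties break toward the lower frequency.  Windows shorter
    than 8 samples — too short for a meaningful spectrum — return the
    documented sentinel 0.0 Hz, as does a constant window (no non-DC
    energy).
    """
    x = np.asarray(window, dtype=float)
    n = len(x)
    if n < MIN_FFT_HISTORY:
        return 0.0
    spectrum = np.abs(np.fft.rfft(x - x.mean()))
    mags = spectrum[1:]
    if mags.max() <= 1e-9 * max(1.0, float(np.abs(x).max())):
        return 0.0
    k = 1 + int(np.argmax(mags))
    return k * sample_rate / n


def _trailing_dominant_freq(x: np.ndarray, fft_window: int, sample_rate: float) -> np.ndarray:
    """Per-sample dominant frequency over the trailing ``fft_window`` samples."""
    n = len(x)
    out = np.zeros(n)
    head_end = min(fft_window - 1, n)
    for i in range(MIN_FFT_HISTORY - 1, head_end):
        out[i] = dominant_frequency(x[: i + 1], sample_rate)
    if n >= fft_window:
        windows = np.lib.stride_tricks.sliding_window_view(x, fft_window)
        centered = windows - windows.mean(axis=1, keepdims=True)
        mags = np.abs(np.fft.rfft(centered, axis=1))[:, 1:]
        k = 1 + np.argmax(mags, axis=1)
        freqs = k * sample_rate / fft_window
        degenerate = mags.max(axis=1) <= 1e-9 * np.maximum(1.0, np.abs(windows).max(axis=1))
        out[fft_window - 1 :] = np.where(degenerate, 0.0, freqs)
    return out


def build_feature_table(
    cohort: list[VitalsSeries],
    smoothing_window: int = 5,
    fft_window: int = 64,
    sample_rate: float = 1.0,
    labeling_config=None,
) -> pd.DataFrame:
    """Assemble the feature table for a noise-corrupted cohort.

    One row per sample: noisy values, trailing rolling means, trailing
    dominant frequencies (sentinel 0.0 Hz while history is under 8
    samples), the subject's context/demographics, and the clean-channel
    ``state`` label.  An ``augmented`` provenance flag (False here) tracks
    rows later added by :func:`time_shift_augment`.
    """
    frames = []
    for series in cohort:
        for ch in _CHANNEL_NAMES:
            if ch not in series.noisy:
                raise ValidationError(
                    f"series {series.profile.subject_id} lacks noisy channel {_CHANNEL_NAMES[ch]}; "
                    "run apply_noise_profile first"
                )
        cols: dict[str, object] = {
            "subject_id": series.profile.subject_id,
            "t": series.t,
        }
        for ch, name in _CHANNEL_NAMES.items():
            x = series.noisy[ch]
            cols[f"{name}_noisy"] = x
            cols[f"{name}_smooth"] = rolling_mean(x, smoothing_window)
            cols[f"{name}_fft"] = _trailing_dominant_freq(x, fft_window, sample_rate)
        cols["Age"] = series.profile.age
        cols["Gender"] = 0 if series.profile.gender == "male" else 1
        cols["Altitude"] = series.context.altitude
        cols["Temperature"] = series.context.temperature
        cols["Activity_level"] = series.context.activity_level
        cols["state"] = label_series(series, labeling_config)
        frames.append(pd.DataFrame(cols))
    table = pd.concat(frames, ignore_index=True)[TABLE_COLUMNS]
    table["augmented"] = False
    return table


def time_shift_augment(table: pd.DataFrame, shifts: list[int]) -> pd.DataFrame:
    """Generate time-shifted training rows (augmented rows only).

    For each shift ``k`` the signal-derived features of a row at time ``t``
    are replaced with those observed at ``t - k``; the label stays at the
    new alignment ``t``.  Edge rows whose source sample does not exist are
    truncated, so each (subject, shift) pair yields ``n_subject - |k|``
    rows, all flagged ``augmented=True``.
    """
    if not shifts:
        raise ValidationError("shift list must be non-empty; augmentation must be explicit")
    lengths = table.groupby("subject_id", sort=False)["t"].size()
    for k in shifts:
        if k == 0:
            raise ValidationError("shift 0 is not allowed")
        if abs(k) >= lengths.min():
            raise ValidationError(
                f"|shift| must be below the shortest series length {lengths.min()}, got {k}"
            )
    out = []
    for _sid, group in table.groupby("subject_id", sort=False):
        group = group.sort_values("t").reset_index(drop=True)
        n = len(group)
        sig = group[SIGNAL_COLUMNS].to_numpy()
        for k in shifts:
            if k > 0:
                dst = group.iloc[k:].copy()
                dst[SIGNAL_COLUMNS] = sig[:-k]
            else:
                dst = group.iloc[: n + k].copy()
                dst[SIGNAL_COLUMNS] = sig[-k:]
            dst["shift"] = k
            out.append(dst)
    augmented = pd.concat(out, ignore_index=True)
    augmented["augmented"] = True
    return augmented
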