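"""Descriptive statistics of a cohort's clean channels.

Small measurement helpers used by the exploratory-analysis surface:
pooled Pearson correlations and histogram mode locations with 1-unit
bins, matching how the reference corpus was characterised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["channel_correlations", "histogram_mode", "bimodal_modes", "cohort_summary"]


def _unit_histogram(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with 1-unit bins centred on integers."""
    values = np.asarray(values, dtype=float)
    lo = np.floor(values.min()) - 0.5
    hi = np.ceil(values.max()) + 1.5
    counts, edges = np.histogram(values, bins=np.arange(lo, hi, 1.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts, centers


def histogram_mode(values: np.ndarray) -> float:
    """Bin centre of the global maximum of the 1-unit-bin histogram."""
    counts, centers = _unit_histogram(values)
    return float(centers[np.argmax(counts)])


def bimodal_modes(values: np.ndarray, min_separation: float = 10.0) -> tuple[float, float]:
    """Locations of the two highest separated local maxima of a histogram.

    The 1-unit-bin counts are smoothed with a centred 5-bin moving average
    before peak picking, which suppresses single-bin sampling jitter without
    shifting a genuine mode.  Local maxima are ranked by height and greedily
    accepted subject to a minimum mutual separation.

    Returns the (lower, upper) mode bin centres.
    """
    counts, centers = _unit_histogram(values)
    smooth = np.convolve(counts, np.ones(5) / 5.0, mode="same")
    is_peak = (smooth >= np.roll(smooth, 1)) & (smooth >= np.roll(smooth, -1))
    is_peak[0] = is_peak[-1] = False
    order = np.argsort(-smooth)
    picked: list[int] = []
    for i in order:
        if not is_peak[i]:
            continue
        if all(abs(centers[i] - centers[j]) >= min_separation for j in picked):
            picked.append(i)
        if len(picked) == 2:
            break
    if len(picked) < 2:
        raise ValueError("histogram does not contain two separated local maxima")
    lo, hi = sorted(centers[i] for i in picked)
    return float(lo), float(hi)


def channel_correlations(frame: pd.DataFrame) -> dict[str, float]:
    """Pooled Pearson correlations of the clean channel pairs of interest."""
    return {
        "hr_pulse": float(np.corrcoef(frame["HR"], frame["Pulse"])[0, 1]),
        "resp_hr": float(np.corrcoef(frame["RESP"], frame["HR"])[0, 1]),
        "spo2_resp": float(np.corrcoef(frame["SpO2"], frame["RESP"])[0, 1]),
    }


def cohort_summary(frame: pd.DataFrame) -> dict[str, float]:
    """Correlations plus histogram mode locations for a cohort frame."""
    hr_lo, hr_hi = bimodal_modes(frame["HR"].to_numpy())
    out = channel_correlations(frame)
    out.update(
        {
            "hr_mode_low": hr_lo,
            "hr_mode_high": hr_hi,
            "resp_mode": histogram_mode(frame["RESP"].to_numpy()),
            "n_rows": int(len(frame)),
            "n_subjects": int(frame["subject_id"].nunique()),
        }
    )
    return out
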