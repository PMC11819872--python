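"""Context-adaptive normal ranges and normal/abnormal labeling.

Each subject gets a personalized :class:`ThresholdSet` computed from
demographics (age, gender) and environment (altitude, temperature,
activity level); a sample is labeled ``abnormal`` when any vital falls
outside its closed normal interval (SpO2 has only a floor).  Labels are
computed from the clean channels, so measurement noise corrupts features
but never the ground truth.

The adjustment rules quantify standard physiology — exertion raises the
acceptable heart-rate/respiratory ceilings, heat adds cardiovascular
strain, aerobic capacity declines slowly with age, altitude lowers the
expected SpO2 baseline — with every coefficient exposed through
:class:`LabelingConfig` for re-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EnvContext, SubjectProfile, VitalsSeries

__all__ = [
    "LabelingConfig",
    "ThresholdSet",
    "compute_thresholds",
    "label_state",
    "label_series",
    "label_cohort",
]


@dataclass(frozen=True)
class LabelingConfig:
    """Coefficients of the context-adjustment rules (units in comments)."""

    hr_lo: float = 60.0                  # bpm, resting floor (HR and pulse)
    hr_hi: float = 100.0                 # bpm, resting ceiling
    resp_lo: float = 12.0                # breaths/min
    resp_hi: float = 20.0                # breaths/min, resting ceiling
    spo2_floor: float = 95.0             # %, sea-level floor
    activity_ceiling_gain: float = 40.0  # bpm per unit activity on the HR ceiling
    activity_floor_drop: float = 10.0    # bpm per unit activity off the HR floor
    resp_activity_gain: float = 10.0     # breaths/min per unit activity on the ceiling
    temp_threshold: float = 30.0         # degrees C above which heat strain starts
    temp_gain: float = 0.5               # bpm ceiling per degree above threshold
    age_threshold: float = 30.0          # years above which max HR declines
    age_slope: float = 0.3               # bpm ceiling per year above threshold
    female_ceiling_bonus: float = 2.0    # bpm added to the HR ceiling
    altitude_threshold: float = 1000.0   # metres above which SpO2 baseline drops
    altitude_drop_per_km: float = 1.5    # % SpO2 floor per 1000 m above threshold


@dataclass(frozen=True)
class ThresholdSet:
    """Context-adjusted normal ranges for one subject (closed intervals)."""

    hr_lo: float
    hr_hi: float
    pulse_lo: float
    pulse_hi: float
    resp_lo: float
    resp_hi: float
    spo2_lo: float

    def __post_init__(self) -> None:
        if not (self.hr_lo < self.hr_hi and self.pulse_lo < self.pulse_hi and self.resp_lo < self.resp_hi):
            raise ValueError("lower bound must be below upper bound for every vital")
        if self.spo2_lo > 100.0:
            raise ValueError("SpO2 floor cannot exceed 100%")


def compute_thresholds(
    profile: SubjectProfile, context: EnvContext, config: LabelingConfig | None = None
) -> ThresholdSet:
    """Personalized normal ranges for one subject in one context.

    With default coefficients: base HR and pulse [60, 100] bpm, RESP
    [12, 20] breaths/min, SpO2 floor 95%; activity ``a`` moves the
    HR/pulse range to [60 - 10a, 100 + 40a] and the RESP ceiling to
    20 + 10a; temperatures above 30 C raise the HR/pulse ceiling by 0.5
    per degree; ages above 30 lower it by 0.3 per year; female subjects
    get +2 bpm of ceiling headroom; altitudes above 1000 m lower the SpO2
    floor by 1.5 per 1000 m.
    """
    c = config or LabelingConfig()
    a = context.activity_level
    hr_hi = c.hr_hi + c.activity_ceiling_gain * a
    hr_hi += c.temp_gain * max(0.0, context.temperature - c.temp_threshold)
    hr_hi -= c.age_slope * max(0.0, profile.age - c.age_threshold)
    if profile.gender == "female":
        hr_hi += c.female_ceiling_bonus
    hr_lo = c.hr_lo - c.activity_floor_drop * a
    resp_hi = c.resp_hi + c.resp_activity_gain * a
    spo2_lo = c.spo2_floor - c.altitude_drop_per_km * max(0.0, context.altitude - c.altitude_threshold) / 1000.0
    return ThresholdSet(
        hr_lo=hr_lo, hr_hi=hr_hi,
        pulse_lo=hr_lo, pulse_hi=hr_hi,
        resp_lo=c.resp_lo, resp_hi=resp_hi,
        spo2_lo=spo2_lo,
    )


def label_state(hr: float, spo2: float, resp: float, pulse: float, thresholds: ThresholdSet) -> str:
    """Label one clean sample: ``abnormal`` iff any vital leaves its range.

    Interval boundaries count as normal; SpO2 is bounded below only.
    """
    t = thresholds
    abnormal = (
        hr < t.hr_lo or hr > t.hr_hi
        or pulse < t.pulse_lo or pulse > t.pulse_hi
        or resp < t.resp_lo or resp > t.resp_hi
        or spo2 < t.spo2_lo
    )
    return "abnormal" if abnormal else "normal"


def label_series(series: VitalsSeries, config: LabelingConfig | None = None) -> np.ndarray:
    """Vectorized per-sample labels for one subject's clean channels."""
    t = compute_thresholds(series.profile, series.context, config)
    abnormal = (
        (series.hr < t.hr_lo) | (series.hr > t.hr_hi)
        | (series.pulse < t.pulse_lo) | (series.pulse > t.pulse_hi)
        | (series.resp < t.resp_lo) | (series.resp > t.resp_hi)
        | (series.spo2 < t.spo2_lo)
    )
    return np.where(abnormal, "abnormal", "normal")


def label_cohort(cohort: list[VitalsSeries], config: LabelingConfig | None = None) -> pd.Series:
    """One label per row of the concatenated cohort, in row order."""
    return pd.Series(
        np.concatenate([label_series(s, config) for s in cohort]), name="state"
    )
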