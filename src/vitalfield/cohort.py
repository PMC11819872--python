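"""Synthetic multi-subject vitals cohort generator.

Emulates the statistical structure of a 53-subject, 8-minute bedside-monitor
corpus sampled at 1 Hz (481 samples per subject, 25,493 rows in total): a
bimodal heart-rate distribution peaking near 80 and 100 bpm, SpO2
concentrated just below 100%, respiratory rate peaking at 18 breaths/min,
and the cross-channel Pearson correlations reported for such data
(HR-pulse 0.97, RESP-HR 0.13, SpO2-RESP -0.30).

Construction
------------
Each subject carries a static demographic profile and environmental context
(altitude, temperature, activity level).  Within a subject, three latent
standard-normal AR(1) processes (HR, RESP, SpO2) share a target correlation
matrix; channel values are monotone transforms of the latents so the
requested correlation structure survives into physical units (a Gaussian
copula).  Activity level selects the subject's heart-rate regime (resting
~80 bpm vs. exerted ~100 bpm), which is what produces the pooled bimodal
histogram, and abnormal physiology is injected as explicit episodes
(tachycardia, desaturation, tachypnea) whose timing, magnitude and
co-occurrence are drawn by a scenario scheduler.

The generator's defaults are calibrated so that the pooled clean columns of
the default cohort reproduce the target marginals and correlations above
while the context-adaptive labeling rules in :mod:`vitalfield.labeling`
flag essentially only the injected episodes as abnormal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from ._seeds import child_seed

__all__ = [
    "SubjectProfile",
    "EnvContext",
    "EpisodeSpec",
    "VitalsSeries",
    "GeneratorConfig",
    "sample_latents",
    "mixture_quantile",
    "inject_episodes",
    "generate_cohort",
    "cohort_to_frame",
]

EPISODE_KINDS = ("tachycardia", "desaturation", "tachypnea")

#: Column order of the long-format cohort CSV.
COHORT_COLUMNS = [
    "subject_id", "t", "HR", "SpO2", "RESP", "Pulse",
    "Age", "Gender", "Altitude", "Temperature", "Activity_level",
]


class ValidationError(ValueError):
    """Raised when a config, profile or episode violates an invariant."""


@dataclass(frozen=True)
class SubjectProfile:
    """Static demographics of one monitored subject."""

    subject_id: str
    age: int          # years, 18..45
    gender: str       # "male" | "female"

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 45:
            raise ValidationError(f"age must be in [18, 45], got {self.age}")
        if self.gender not in ("male", "female"):
            raise ValidationError(f"gender must be 'male' or 'female', got {self.gender!r}")


@dataclass(frozen=True)
class EnvContext:
    """Environmental context, constant over one 8-minute record."""

    altitude: float          # metres above sea level
    temperature: float       # ambient, degrees Celsius
    activity_level: float    # unitless fraction in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.altitude <= 9000.0:
            raise ValidationError(f"altitude must be in [0, 9000] m, got {self.altitude}")
        if not -40.0 <= self.temperature <= 60.0:
            raise ValidationError(f"temperature must be in [-40, 60] C, got {self.temperature}")
        if not 0.0 <= self.activity_level <= 1.0:
            raise ValidationError(f"activity_level must be in [0, 1], got {self.activity_level}")


@dataclass(frozen=True)
class EpisodeSpec:
    """One injected abnormal episode on a single vital channel.

    ``magnitude`` is expressed in the affected channel's units and is applied
    over ``[start, start + duration)`` seconds: tachycardia adds to HR and
    pulse, desaturation subtracts from SpO2 (floored at 70%), tachypnea adds
    to RESP.
    """

    kind: str
    start: int        # seconds from series start
    duration: int     # seconds, > 0
    magnitude: float  # channel units

    def __post_init__(self) -> None:
        if self.kind not in EPISODE_KINDS:
            raise ValidationError(f"unknown episode kind {self.kind!r}; expected one of {EPISODE_KINDS}")
        if self.start < 0:
            raise ValidationError(f"episode start must be >= 0, got {self.start}")
        if self.duration <= 0:
            raise ValidationError(f"episode duration must be > 0, got {self.duration}")


@dataclass
class VitalsSeries:
    """One subject's 1 Hz clean vitals record plus profile and context.

    Channels are stored as float arrays aligned with ``t`` (strictly
    increasing, 1-second spacing).  ``noisy`` holds the measurement-corrupted
    channels once :func:`vitalfield.noise.apply_noise_profile` has run.
    """

    profile: SubjectProfile
    context: EnvContext
    t: np.ndarray
    hr: np.ndarray
    spo2: np.ndarray
    resp: np.ndarray
    pulse: np.ndarray
    episodes: list[EpisodeSpec] = field(default_factory=list)
    noisy: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        n = len(self.t)
        for name in ("hr", "spo2", "resp", "pulse"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"channel {name} length != len(t)")
        if n > 1 and not np.all(np.diff(self.t) == 1):
            raise ValidationError("t must increase in constant 1 s steps")
        if np.any(self.spo2 > 100.0 + 1e-9):
            raise ValidationError("SpO2 exceeds 100%")

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per sample (clean channels)."""
        return pd.DataFrame(
            {
                "subject_id": self.profile.subject_id,
                "t": self.t,
                "HR": self.hr,
                "SpO2": self.spo2,
                "RESP": self.resp,
                "Pulse": self.pulse,
                "Age": self.profile.age,
                "Gender": 0 if self.profile.gender == "male" else 1,
                "Altitude": self.context.altitude,
                "Temperature": self.context.temperature,
                "Activity_level": self.context.activity_level,
            }
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Tunable parameters of the cohort generator.

    The defaults reproduce the reference corpus dimensions (53 subjects x
    481 samples = 25,493 rows) and are calibrated so the pooled clean
    columns hit the target marginals and correlations.  ``latent_correlations``
    orders the latents (HR, RESP, SpO2); it is the *within-subject* latent
    target — the pooled observed correlations also inherit between-subject
    context variance and episode co-occurrence, which the calibration
    accounts for.
    """

    n_subjects: int = 53
    samples_per_subject: int = 481
    latent_correlations: tuple[tuple[float, float, float], ...] = (
        (1.0, 0.50, 0.0),
        (0.50, 1.0, -0.75),
        (0.0, -0.75, 1.0),
    )
    # HR mixture: (mean_low, mean_high, sd_low, sd_high, weight_low)
    hr_mixture: tuple[float, float, float, float, float] = (80.0, 100.0, 6.0, 6.0, 0.5)
    pulse_noise_sd: float = 5.5
    episode_rate: float = 3.2          # expected scenario events per subject
    abnormal_target_fraction: float = 0.30
    seed: int = 42

    # --- shape of the within-subject dynamics -------------------------------
    ar_coeff: float = 0.95             # AR(1) smoothing of each latent
    # --- channel transforms -------------------------------------------------
    hr_activity_slope: float = 6.0    # bpm per unit activity within a regime
    resp_base: float = 18.0            # breaths/min
    resp_scale: float = 1.2            # breaths/min per latent sd
    resp_activity_gain: float = 1.0    # breaths/min per unit activity
    spo2_base: float = 97.5            # %
    spo2_scale: float = 1.0            # % per latent sd
    spo2_altitude_drop: float = 1.5    # % per 1000 m above 1000 m
    # --- context sampling ---------------------------------------------------
    altitude_range: tuple[float, float] = (0.0, 3000.0)
    temperature_range: tuple[float, float] = (-10.0, 45.0)
    # --- episode scenario scheduler ----------------------------------------
    scenario_weights: tuple[float, float, float] = (0.40, 0.35, 0.25)
    # exertion / hypoxia / hyperventilation
    duration_range: tuple[int, int] = (30, 60)

    def corr_matrix(self) -> np.ndarray:
        return np.asarray(self.latent_correlations, dtype=float)

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.samples_per_subject < 1:
            raise ValidationError(f"samples_per_subject must be >= 1, got {self.samples_per_subject}")
        _check_corr(self.corr_matrix())
        if self.pulse_noise_sd < 0:
            raise ValidationError("pulse_noise_sd must be >= 0")
        if self.episode_rate < 0:
            raise ValidationError("episode_rate must be >= 0")
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValidationError("ar_coeff must be in [0, 1)")
        lo, hi = self.duration_range
        if not (0 < lo <= hi):
            raise ValidationError("duration_range must satisfy 0 < lo <= hi")
        if abs(sum(self.scenario_weights) - 1.0) > 1e-9:
            raise ValidationError("scenario_weights must sum to 1")


def _check_corr(corr: np.ndarray) -> None:
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (3, 3):
        raise ValidationError(f"correlation matrix must be 3x3, got shape {corr.shape}")
    if not np.allclose(corr, corr.T, atol=1e-12):
        raise ValidationError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
        raise ValidationError("correlation matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals[0] < -1e-10:
        raise ValidationError(
            f"correlation matrix is not positive semi-definite: smallest eigenvalue {eigvals[0]:.6g}"
        )


def sample_latents(n: int, corr: np.ndarray, seed: int) -> np.ndarray:
    """Draw ``n`` jointly Gaussian (HR, RESP, SpO2) latent triples.

    This is the copula core: standard-normal marginals with the requested
    3x3 correlation.  Reproducible for a fixed ``seed``.

    Returns an ``(n, 3)`` array.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    corr = np.asarray(corr, dtype=float)
    _check_corr(corr)
    rng = np.random.default_rng(seed)
    # eigendecomposition square root tolerates exactly-singular matrices
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((n, 3))
    return z @ root.T


def mixture_quantile(u, means=(80.0, 100.0), sd: float = 6.0, weight: float = 0.5):
    """Inverse CDF of the equal-sd two-component normal heart-rate mixture.

    Parameters
    ----------
    u:
        Probability (scalar or array) strictly inside (0, 1).
    means:
        Component means in bpm (defaults 80 and 100).
    sd:
        Common component standard deviation in bpm.
    weight:
        Weight of the first (lower) component.

    The equal-weight default is symmetric about the midpoint, so
    ``mixture_quantile(0.5) == 90``.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= 0.0) or np.any(u_arr >= 1.0):
        raise ValidationError("u must lie strictly inside (0, 1)")
    m1, m2 = means

    def cdf(x):
        return weight * norm.cdf(x, m1, sd) + (1.0 - weight) * norm.cdf(x, m2, sd)

    lo = min(m1, m2) - 10.0 * sd
    hi = max(m1, m2) + 10.0 * sd
    out = np.empty_like(u_arr)
    for idx, ui in np.ndenumerate(u_arr):
        out[idx] = brentq(lambda x, ui=ui: cdf(x) - ui, lo, hi, xtol=1e-10)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out


def inject_episodes(series: VitalsSeries, specs: list[EpisodeSpec]) -> VitalsSeries:
    """Return a copy of ``series`` with abnormal episodes applied.

    Tachycardia adds ``magnitude`` bpm to HR and pulse, desaturation
    subtracts ``magnitude`` from SpO2 (floored at 70%), tachypnea adds
    ``magnitude`` to RESP — each over ``[start, start + duration)``.
    Episodes of the same kind must not overlap; different kinds may
    co-occur (e.g. a hypoxic event that both desaturates and raises the
    respiratory rate).
    """
    n = len(series)
    by_kind: dict[str, list[EpisodeSpec]] = {}
    for spec in specs:
        if spec.start + spec.duration > n:
            raise ValidationError(
                f"episode {spec.kind} [{spec.start}, {spec.start + spec.duration}) "
                f"exceeds series length {n}"
            )
        by_kind.setdefault(spec.kind, []).append(spec)
    for kind, group in by_kind.items():
        group = sorted(group, key=lambda s: s.start)
        for a, b in zip(group, group[1:]):
            if a.start + a.duration > b.start:
                raise ValidationError(f"overlapping {kind} episodes at t={b.start}")

    out = replace(
        series,
        hr=series.hr.copy(),
        spo2=series.spo2.copy(),
        resp=series.resp.copy(),
        pulse=series.pulse.copy(),
        episodes=list(series.episodes) + list(specs),
        noisy=dict(series.noisy),
    )
    for spec in specs:
        sl = slice(spec.start, spec.start + spec.duration)
        if spec.kind == "tachycardia":
            out.hr[sl] += spec.magnitude
            out.pulse[sl] += spec.magnitude
        elif spec.kind == "desaturation":
            out.spo2[sl] = np.maximum(out.spo2[sl] - spec.magnitude, 70.0)
        else:  # tachypnea
            out.resp[sl] += spec.magnitude
    return out


def _sample_context(rng: np.random.Generator, config: GeneratorConfig) -> EnvContext:
    alt = rng.uniform(*config.altitude_range)
    temp = rng.uniform(*config.temperature_range)
    act = rng.uniform(0.0, 1.0)
    return EnvContext(altitude=alt, temperature=temp, activity_level=act)


def _sample_profile(rng: np.random.Generator, idx: int) -> SubjectProfile:
    age = int(rng.integers(18, 46))
    gender = "female" if rng.random() < 0.5 else "male"
    return SubjectProfile(subject_id=f"S{idx:03d}", age=age, gender=gender)


def _ar1_latents(eps: np.ndarray, phi: float) -> np.ndarray:
    """Turn iid correlated innovations into stationary AR(1) latent paths.

    ``eps`` has shape (n+1, 3); row 0 initialises the chain at its
    stationary distribution.  Each channel keeps a unit marginal variance
    and the cross-channel correlation of the innovations.
    """
    n = eps.shape[0] - 1
    z = np.empty((n, 3))
    state = eps[0]
    scale = math.sqrt(1.0 - phi * phi)
    for i in range(n):
        state = phi * state + scale * eps[i + 1]
        z[i] = state
    return z


def _schedule_scenarios(
    rng: np.random.Generator, config: GeneratorConfig, context: EnvContext, n: int
) -> list[EpisodeSpec]:
    """Draw this subject's abnormal-episode scenario list.

    Three physiologic archetypes, chosen per event with ``scenario_weights``:

    * exertion  — tachycardia whose magnitude grows with the activity level
      (so it clears the activity-raised HR ceiling), with a mild respiratory
      co-elevation;
    * hypoxia   — desaturation with a compensatory respiratory co-elevation;
    * hyperventilation — isolated tachypnea.

    Same-kind episodes are kept disjoint; co-occurring kinds inside one
    event are intentional and physiological.

    Event kinds are stratified: every full block of three events contains
    one event of each archetype (in random order), and any fractional
    remainder is drawn with ``scenario_weights``.  This keeps the cohort's
    episode composition stable across seeds without making any individual
    record deterministic.
    """
    a = context.activity_level
    base = int(config.episode_rate)
    n_events = base + int(rng.random() < (config.episode_rate - base))
    scenario_kinds = []
    for block in range(0, n_events - n_events % 3, 3):
        scenario_kinds.extend(rng.permutation(3).tolist())
    for _ in range(n_events % 3):
        scenario_kinds.append(int(rng.choice(3, p=np.asarray(config.scenario_weights))))
    lo_d, hi_d = config.duration_range
    occupied: dict[str, list[tuple[int, int]]] = {k: [] for k in EPISODE_KINDS}

    def fits(kind: str, start: int, dur: int) -> bool:
        return all(start + dur <= s or start >= s + d for s, d in occupied[kind])

    specs: list[EpisodeSpec] = []
    for kind_idx in scenario_kinds:
        dur = int(rng.integers(lo_d, hi_d + 1))
        if dur >= n:
            continue
        placed = None
        for _try in range(50):
            start = int(rng.integers(0, n - dur + 1))
            if kind_idx == 0:
                kinds = [("tachycardia", 40.0 + 40.0 * a), ("tachypnea", 3.3)]
            elif kind_idx == 1:
                kinds = [("desaturation", 8.0), ("tachypnea", 6.5)]
            else:
                kinds = [("tachypnea", 10.0 + 10.0 * a)]
            if all(fits(k, start, dur) for k, _ in kinds):
                placed = (start, kinds, dur)
                break
        if placed is None:
            continue
        start, kinds, dur = placed
        for k, mag in kinds:
            occupied[k].append((start, dur))
            specs.append(EpisodeSpec(kind=k, start=start, duration=dur, magnitude=mag))
    return specs


def _generate_series(config: GeneratorConfig, idx: int) -> VitalsSeries:
    n = config.samples_per_subject
    rng = np.random.default_rng(child_seed(config.seed, "subject", idx))
    profile = _sample_profile(rng, idx)
    context = _sample_context(rng, config)

    eps = sample_latents(n + 1, config.corr_matrix(), child_seed(config.seed, "latents", idx))
    z = _ar1_latents(eps, config.ar_coeff)

    a = context.activity_level
    m_lo, m_hi, sd_lo, sd_hi, _w = config.hr_mixture
    # Activity selects the heart-rate regime: resting subjects sit in the
    # lower mixture component, exerted subjects in the upper one.  Uniform
    # activity therefore reproduces the equal-weight pooled bimodality while
    # keeping every subject well inside its context-adjusted normal range.
    if a > 0.5:
        mu, sd, center = m_hi, sd_hi, 0.75
    else:
        mu, sd, center = m_lo, sd_lo, 0.25
    hr = mu + config.hr_activity_slope * (a - center) + sd * z[:, 0]
    resp = config.resp_base + config.resp_activity_gain * (a - 0.5) + config.resp_scale * z[:, 1]
    drop = config.spo2_altitude_drop * max(0.0, context.altitude - 1000.0) / 1000.0
    spo2 = np.minimum(config.spo2_base + config.spo2_scale * z[:, 2] - drop, 100.0)
    pulse = hr + config.pulse_noise_sd * rng.standard_normal(n)

    series = VitalsSeries(
        profile=profile,
        context=context,
        t=np.arange(n, dtype=int),
        hr=hr,
        spo2=spo2,
        resp=np.maximum(resp, 1.0),
        pulse=np.maximum(pulse, 1.0),
    )
    ep_rng = np.random.default_rng(child_seed(config.seed, "episodes", idx))
    specs = _schedule_scenarios(ep_rng, config, context, n)
    return inject_episodes(series, specs)


def generate_cohort(config: GeneratorConfig | None = None) -> list[VitalsSeries]:
    """Generate the full synthetic cohort.

    With the default configuration this yields 53 series of 481 samples
    each — 25,493 rows in total.  The output is a pure function of the
    config (including its seed).
    """
    config = config or GeneratorConfig()
    config.validate()
    return [_generate_series(config, i) for i in range(config.n_subjects)]


def cohort_to_frame(cohort: list[VitalsSeries]) -> pd.DataFrame:
    """Concatenate a cohort into one long-format clean-channel frame."""
    return pd.concat([s.to_frame() for s in cohort], ignore_index=True)[COHORT_COLUMNS]
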