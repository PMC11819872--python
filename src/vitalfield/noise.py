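"""Measurement-noise models for field-condition vitals.

Three corruption processes emulate field sensor behaviour: additive
Gaussian noise (electronic fluctuation), salt-and-pepper replacement
(spikes and dropouts), and a low-frequency sinusoid on the respiratory
channel (slow periodic interference).  The composition order is fixed:
Gaussian, then salt-and-pepper, then periodic; every operator with zero
parameters is the identity, and a fixed seed reproduces the full noisy
cohort bit for bit.

Noise is applied after episode injection, so abnormal rows are corrupted
like any other, and the clean channels are kept alongside the noisy ones:
features are computed from noisy signals while ground-truth labels come
from clean ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import child_seed
from .cohort import ValidationError, VitalsSeries

__all__ = [
    "NoiseConfig",
    "add_gaussian_noise",
    "add_salt_pepper",
    "add_periodic",
    "apply_noise_profile",
]

CHANNELS = ("hr", "spo2", "resp", "pulse")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel noise magnitudes.

    Defaults are small relative to the labeling margins, so the state of a
    sample remains learnable from its corrupted features.
    """

    gaussian_sd: dict[str, float] = field(
        default_factory=lambda: {"hr": 2.0, "pulse": 2.0, "resp": 1.0, "spo2": 0.5}
    )
    salt_pepper_prob: float = 0.01
    salt_pepper_extremes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hr": (30.0, 200.0),
            "pulse": (30.0, 200.0),
            "resp": (4.0, 40.0),
            "spo2": (70.0, 100.0),
        }
    )
    periodic_amplitude: float = 1.0   # breaths/min, RESP only
    periodic_frequency: float = 0.05  # Hz
    sample_rate: float = 1.0          # Hz
    seed: int = 0

    def validate(self) -> None:
        for ch in CHANNELS:
            if self.gaussian_sd.get(ch, 0.0) < 0:
                raise ValidationError(f"gaussian sd for {ch} must be >= 0")
            lo, hi = self.salt_pepper_extremes.get(ch, (0.0, 1.0))
            if lo >= hi:
                raise ValidationError(f"salt-pepper extremes for {ch} must satisfy low < high")
        if not 0.0 <= self.salt_pepper_prob <= 1.0:
            raise ValidationError("salt_pepper_prob must be in [0, 1]")
        if self.periodic_amplitude < 0:
            raise ValidationError("periodic amplitude must be >= 0")
        if self.periodic_frequency < 0:
            raise ValidationError("periodic frequency must be >= 0")
        if self.periodic_frequency >= self.sample_rate / 2.0:
            raise ValidationError(
                f"periodic frequency {self.periodic_frequency} Hz is at or above the "
                f"Nyquist limit {self.sample_rate / 2.0} Hz"
            )


def add_gaussian_noise(series, sd: float, seed: int) -> np.ndarray:
    """Add iid Normal(0, sd) to every sample; ``sd=0`` is the identity."""
    if sd < 0:
        raise ValidationError(f"sd must be >= 0, got {sd}")
    x = np.asarray(series, dtype=float)
    if sd == 0:
        return x.copy()
    rng = np.random.default_rng(seed)
    return x + rng.normal(0.0, sd, size=x.shape)


def add_salt_pepper(series, p: float, low: float, high: float, seed: int) -> np.ndarray:
    """Replace each sample with probability ``p`` by ``low`` or ``high``.

    Replacement value is low or high with equal probability; untouched
    samples pass through unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must be in [0, 1], got {p}")
    if low >= high:
        raise ValidationError(f"low must be < high, got low={low}, high={high}")
    x = np.asarray(series, dtype=float).copy()
    if p == 0:
        return x
    rng = np.random.default_rng(seed)
    hit = rng.random(x.shape) < p
    salt = rng.random(x.shape) < 0.5
    x[hit & salt] = high
    x[hit & ~salt] = low
    return x


def add_periodic(series, amplitude: float, frequency: float, sample_rate: float = 1.0) -> np.ndarray:
    """Add a zero-phase sinusoid ``amplitude * sin(2*pi*f*i/fs)``.

    Deterministic; models slow periodic interference on the respiratory
    channel.  Frequencies at or above Nyquist are rejected.
    """
    if amplitude < 0:
        raise ValidationError(f"amplitude must be >= 0, got {amplitude}")
    if frequency >= sample_rate / 2.0:
        raise ValidationError(
            f"frequency {frequency} Hz is at or above the Nyquist limit {sample_rate / 2.0} Hz"
        )
    x = np.asarray(series, dtype=float)
    i = np.arange(len(x))
    return x + amplitude * np.sin(2.0 * np.pi * frequency * i / sample_rate)


def apply_noise_profile(
    cohort: list[VitalsSeries], config: NoiseConfig | None = None
) -> list[VitalsSeries]:
    """Attach noisy channels to every series of a cohort (in place).

    Per channel: Gaussian noise, then salt-and-pepper; the RESP channel
    additionally receives the periodic component.  Noisy SpO2 is clipped
    to 100%.  Returns the cohort for chaining.
    """
    config = config or NoiseConfig()
    config.validate()
    for idx, series in enumerate(cohort):
        for ch in CHANNELS:
            x = getattr(series, ch)
            x = add_gaussian_noise(x, config.gaussian_sd[ch], child_seed(config.seed, "gauss", ch, idx))
            lo, hi = config.salt_pepper_extremes[ch]
            x = add_salt_pepper(
                x, config.salt_pepper_prob, lo, hi, child_seed(config.seed, "sp", ch, idx)
            )
            if ch == "resp":
                x = add_periodic(x, config.periodic_amplitude, config.periodic_frequency, config.sample_rate)
            if ch == "spo2":
                x = np.minimum(x, 100.0)
            series.noisy[ch] = x
    return cohort
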