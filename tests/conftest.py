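"""Shared fixtures.

Heavy artefacts — the default-size cohort, its feature table, and a
deployed gradient-boosting model — are built once per session; unit
tests use a smaller eight-subject cohort.
"""

from __future__ import annotations

import numpy as np
import pytest

from vitalfield.classify import ModelSpec, train_and_evaluate
from vitalfield.cohort import (
    EnvContext,
    GeneratorConfig,
    SubjectProfile,
    VitalsSeries,
    generate_cohort,
    cohort_to_frame,
)
from vitalfield.features import build_feature_table
from vitalfield.noise import apply_noise_profile
from vitalfield.secure import KeyConfig

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def default_cohort():
    """The default 53-subject, 481-sample cohort with noisy channels attached."""
    cohort = generate_cohort(GeneratorConfig(seed=DEFAULT_SEED))
    apply_noise_profile(cohort)
    return cohort


@pytest.fixture(scope="session")
def default_frame(default_cohort):
    return cohort_to_frame(default_cohort)


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return build_feature_table(default_cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight subjects, 200 samples: fast but statistically non-trivial."""
    cohort = generate_cohort(GeneratorConfig(n_subjects=8, samples_per_subject=200, seed=7))
    apply_noise_profile(cohort)
    return cohort


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return build_feature_table(small_cohort)


@pytest.fixture(scope="session")
def tiny_model_path(small_table, tmp_path_factory):
    """A quick gradient-boosting model persisted for the simulator tests."""
    path = tmp_path_factory.mktemp("models") / "tiny_gb.joblib"
    train_and_evaluate(
        small_table,
        ModelSpec("gradient_boosting", {"n_estimators": 80}, seed=7),
        seed=7,
        model_path=str(path),
    )
    return str(path)


@pytest.fixture(scope="session")
def deployed_model(default_table, tmp_path_factory):
    """The full-protocol gradient-boosting model and its held-out report."""
    path = tmp_path_factory.mktemp("models") / "gb_default.joblib"
    report = train_and_evaluate(
        default_table,
        ModelSpec("gradient_boosting", seed=DEFAULT_SEED),
        seed=DEFAULT_SEED,
        model_path=str(path),
    )
    return str(path), report


@pytest.fixture()
def squad_key():
    return KeyConfig(key=bytes(range(16)), key_id="test-squad")


def make_constant_series(
    n: int = 100,
    hr: float = 75.0,
    spo2: float = 98.0,
    resp: float = 16.0,
    pulse: float = 75.0,
    with_noise_alias: bool = True,
) -> VitalsSeries:
    """A hand-built series with constant, safely in-range vitals."""
    series = VitalsSeries(
        profile=SubjectProfile(subject_id="CONST", age=25, gender="male"),
        context=EnvContext(altitude=0.0, temperature=20.0, activity_level=0.3),
        t=np.arange(n, dtype=int),
        hr=np.full(n, hr),
        spo2=np.full(n, spo2),
        resp=np.full(n, resp),
        pulse=np.full(n, pulse),
    )
    if with_noise_alias:
        series.noisy = {
            "hr": series.hr.copy(),
            "spo2": series.spo2.copy(),
            "resp": series.resp.copy(),
            "pulse": series.pulse.copy(),
        }
    return series
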