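"""Run configuration and dataset serialization.

A single JSON file configures every stage under its own key (``generator``,
``noise``, ``labeling``, ``models``, ``security``, ``simulation``) plus a
global ``seed`` that fans out to per-stage child seeds.  Unknown keys and
invariant violations are rejected with the JSON path of the offender.

Datasets travel as CSV with bit-exact headers: the long-format cohort and
the 17-feature + ``state`` table; reads are strict about column presence
and order and round-trip values beyond 10 decimal places.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .cohort import COHORT_COLUMNS, EpisodeSpec, GeneratorConfig, ValidationError
from .features import TABLE_COLUMNS
from .labeling import LabelingConfig
from .noise import NoiseConfig
from .secure import KeyConfig
from .simulation import SimConfig

__all__ = [
    "RunConfig",
    "ModelsConfig",
    "load_config",
    "write_dataset",
    "read_dataset",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class ModelsConfig:
    """Evaluation-protocol settings shared by the classifier benchmark."""

    test_fraction: float = 0.2
    k_folds: int = 5
    seed: int = 42
    augment_shifts: tuple[int, ...] = (-3, -2, -1, 1, 2, 3)

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must be in (0, 1)")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full run."""

    generator: GeneratorConfig
    noise: NoiseConfig
    labeling: LabelingConfig
    models: ModelsConfig
    simulation: SimConfig
    security: KeyConfig | None
    seed: int

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name == "security":
                out[f.name] = None if value is None else {"key_id": value.key_id, "key_hex": "***"}
            elif dataclasses.is_dataclass(value):
                out[f.name] = dataclasses.asdict(value)
            else:
                out[f.name] = value
        return out


_TUPLE_FIELDS = {
    "latent_correlations": lambda v: tuple(tuple(map(float, row)) for row in v),
    "hr_mixture": lambda v: tuple(map(float, v)),
    "altitude_range": lambda v: tuple(map(float, v)),
    "temperature_range": lambda v: tuple(map(float, v)),
    "scenario_weights": lambda v: tuple(map(float, v)),
    "duration_range": lambda v: tuple(map(int, v)),
    "augment_shifts": lambda v: tuple(map(int, v)),
    "hidden_layer_sizes": lambda v: tuple(map(int, v)),
}


def _build_section(cls, data: dict, path: str, converters: dict | None = None):
    field_names = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in field_names:
            raise ValidationError(f"unknown key at {path}.{key}")
    kwargs = {}
    for key, value in data.items():
        if key in _TUPLE_FIELDS:
            value = _TUPLE_FIELDS[key](value)
        if converters and key in converters:
            value = converters[key](value)
        kwargs[key] = value
    try:
        obj = cls(**kwargs)
        if hasattr(obj, "validate"):
            obj.validate()
    except (ValidationError, ValueError, TypeError) as exc:
        raise ValidationError(f"invalid section {path}: {exc}") from exc
    return obj


def _parse_security(data: dict, path: str) -> KeyConfig:
    allowed = {"key_hex", "key_id"}
    for key in data:
        if key not in allowed:
            raise ValidationError(f"unknown key at {path}.{key}")
    key_hex = data.get("key_hex")
    if key_hex is None:
        raise ValidationError(f"{path}.key_hex is required when a security section is present")
    if len(key_hex) != 32:
        raise ValidationError(
            f"{path}.key_hex must be 32 hex characters (16 bytes), got {len(key_hex)}"
        )
    return KeyConfig.from_hex(key_hex, data.get("key_id", "squad-key"))


def _parse_simulation(data: dict, path: str) -> SimConfig:
    converters = {
        "outages": lambda v: {
            node: [tuple(map(int, win)) for win in wins] for node, wins in v.items()
        },
        "forced_episodes": lambda v: {
            node: [EpisodeSpec(**spec) for spec in specs] for node, specs in v.items()
        },
        "noise": lambda v: _build_section(NoiseConfig, v, f"{path}.noise"),
    }
    return _build_section(SimConfig, data, path, converters)


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a JSON run configuration.

    An empty JSON object yields all defaults (53 subjects, 481 samples per
    subject, 5-second simulation tick, no pre-shared key).  Every section
    is validated by its owning module; errors name the JSON path of the
    first offender.
    """
    if isinstance(path_or_dict, dict):
        raw = path_or_dict
    else:
        with open(path_or_dict) as fh:
            raw = json.load(fh)
    known = {"generator", "noise", "labeling", "models", "security", "simulation", "seed"}
    for key in raw:
        if key not in known:
            raise ValidationError(f"unknown key at {key}")
    seed = int(raw.get("seed", 42))

    def section(name, default):
        data = dict(raw.get(name, {}))
        if name in ("generator", "noise", "simulation") and "seed" not in data:
            data["seed"] = child_seed(seed, name)
        if name == "simulation":
            return _parse_simulation(data, name)
        return _build_section(type(default), data, name)

    security = None
    if "security" in raw:
        security = _parse_security(dict(raw["security"]), "security")
    return RunConfig(
        generator=section("generator", GeneratorConfig()),
        noise=section("noise", NoiseConfig()),
        labeling=section("labeling", LabelingConfig()),
        models=section("models", ModelsConfig()),
        simulation=section("simulation", SimConfig()),
        security=security,
        seed=seed,
    )


def _check_schema(frame: pd.DataFrame, expected: list[str], path: str) -> None:
    got = list(frame.columns)
    for i, name in enumerate(expected):
        if i >= len(got) or got[i] != name:
            found = got[i] if i < len(got) else "<missing>"
            raise ValidationError(
                f"{path}: schema mismatch at column {i}: expected {name!r}, found {found!r}"
            )
    if len(got) > len(expected):
        raise ValidationError(f"{path}: unexpected extra column {got[len(expected)]!r}")


def write_dataset(table: pd.DataFrame, path: str) -> None:
    """Write a feature table as CSV with the canonical header."""
    table[TABLE_COLUMNS].to_csv(path, index=False)


def read_dataset(path: str) -> pd.DataFrame:
    """Read a feature-table CSV, enforcing the exact column layout."""
    frame = pd.read_csv(path)
    _check_schema(frame, TABLE_COLUMNS, str(path))
    if frame[TABLE_COLUMNS].isna().any().any():
        raise ValidationError(f"{path}: table contains missing values")
    frame["augmented"] = False
    return frame


def write_cohort(frame: pd.DataFrame, path: str) -> None:
    """Write a long-format clean cohort CSV."""
    frame[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str) -> pd.DataFrame:
    """Read a long-format cohort CSV, enforcing the exact column layout."""
    frame = pd.read_csv(path)
    _check_schema(frame, COHORT_COLUMNS, str(path))
    return frame
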