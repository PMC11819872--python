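"""State classifiers: training, stratified evaluation, persistence.

Six binary classifiers predict ``normal``/``abnormal`` from the 17-column
feature table: logistic regression (baseline), k-nearest neighbours,
random forest, gradient boosting, XGBoost (optional at runtime) and a
multi-layer perceptron.  Evaluation uses a stratified train/test split
with stratified k-fold cross-validation on the training portion, weighted
precision/recall/F1, and a confusion matrix oriented with ``abnormal`` as
the positive class.

Time-shift-augmented rows are training-only: the split and every fold are
formed from original rows, and an augmented row is admitted to the
training set only when both its label row and its feature-source row
belong to the training portion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_score,
    recall_score,
    f1_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import ValidationError
from .features import FEATURE_COLUMNS, time_shift_augment

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "EvalReport",
    "build_model",
    "split_stratified",
    "cross_validate",
    "train_and_evaluate",
    "benchmark_all",
    "save_model",
    "load_model",
]

MODEL_NAMES = (
    "logistic_regression",
    "knn",
    "random_forest",
    "gradient_boosting",
    "xgboost",
    "mlp",
)

DISPLAY_NAMES = {
    "logistic_regression": "Logistic Regression",
    "knn": "k-Nearest Neighbors",
    "random_forest": "Random Forest",
    "gradient_boosting": "Gradient Boosting",
    "xgboost": "XGBoost",
    "mlp": "MultiLayer Perceptron",
}

DEFAULT_SHIFTS = (-3, -2, -1, 1, 2, 3)

PERSIST_FORMAT_VERSION = 1


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier with fixed hyperparameters and a seed."""

    name: str
    hyperparameters: dict = dc_field(default_factory=dict)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValidationError(
                f"unknown model {self.name!r}; valid names: {', '.join(MODEL_NAMES)}"
            )


@dataclass
class EvalReport:
    """Held-out evaluation of one model.

    ``confusion`` rows/columns are ordered (abnormal, normal): entry [0, 0]
    counts true abnormals predicted abnormal.  Precision, recall and F1 are
    class-frequency-weighted averages.
    """

    model: str
    seed: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    n_test: int
    per_fold_metrics: list[dict] = dc_field(default_factory=list)
    error: str | None = None


def build_model(spec: ModelSpec):
    """Instantiate the scikit-learn (or XGBoost) estimator for a spec.

    Distance- and gradient-based models standardise inputs inside their
    pipeline; tree ensembles consume raw features.
    """
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    if spec.name == "logistic_regression":
        est = LogisticRegression(C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 1000), **hp)
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.name == "knn":
        est = KNeighborsClassifier(
            n_neighbors=hp.pop("n_neighbors", 15), weights=hp.pop("weights", "distance"), **hp
        )
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    if spec.name == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 300), random_state=seed, n_jobs=1, **hp
        )
    if spec.name == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 300),
            learning_rate=hp.pop("learning_rate", 0.1),
            max_depth=hp.pop("max_depth", 3),
            random_state=seed,
            **hp,
        )
    if spec.name == "xgboost":
        try:
            from xgboost import XGBClassifier
        except ImportError as exc:  # pragma: no cover - depends on environment
            raise ImportError("xgboost is not installed; install the 'xgboost' extra") from exc
        return XGBClassifier(
            n_estimators=hp.pop("n_estimators", 300),
            learning_rate=hp.pop("learning_rate", 0.1),
            max_depth=hp.pop("max_depth", 4),
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
            **hp,
        )
    if spec.name == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (64, 32)),
            early_stopping=hp.pop("early_stopping", True),
            random_state=seed,
            **hp,
        )
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    raise ValidationError(f"unknown model {spec.name!r}")  # unreachable after ModelSpec check


def _xy(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    y = np.where(table["state"].to_numpy() == "abnormal", 1, 0)
    return table[FEATURE_COLUMNS], y


def _check_two_classes(table: pd.DataFrame) -> None:
    classes = set(table["state"].unique())
    if len(classes) < 2:
        raise ValidationError(
            f"stratification impossible: table contains a single class {classes}"
        )


def split_stratified(
    table: pd.DataFrame, test_fraction: float = 0.2, seed: int = 42
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split of the original (non-augmented) rows.

    Class proportions in both parts match the table's to within one row.
    Any augmented rows present are routed to the training side, never the
    test side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError(f"test_fraction must be in (0, 1), got {test_fraction}")
    aug_col = table["augmented"] if "augmented" in table.columns else pd.Series(False, index=table.index)
    base = table[~aug_col]
    _check_two_classes(base)
    class_counts = base["state"].value_counts()
    if class_counts.min() >= 2:
        train, test = train_test_split(
            base, test_size=test_fraction, stratify=base["state"], random_state=seed
        )
    else:
        # degenerate stratification (a one-member class): split each class
        # proportionally by largest remainder, deterministically under seed
        rng = np.random.default_rng(seed)
        n_test_total = int(round(len(base) * test_fraction))
        test_idx = []
        for cls, group in base.groupby("state", sort=True):
            take = int(round(len(group) * test_fraction))
            perm = rng.permutation(len(group))
            test_idx.extend(group.index[perm[:take]])
        while len(test_idx) < max(1, n_test_total) and len(test_idx) < len(base) - 1:
            remaining = base.index.difference(test_idx)
            test_idx.append(remaining[0])
        test = base.loc[test_idx]
        train = base.drop(index=test_idx)
    train = pd.concat([train, table[aug_col.astype(bool)]], ignore_index=False)
    return train, test


def _metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    return {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(precision_score(y_true, y_pred, average="weighted", zero_division=0)),
        "recall": float(recall_score(y_true, y_pred, average="weighted", zero_division=0)),
        "f1": float(f1_score(y_true, y_pred, average="weighted", zero_division=0)),
    }


def cross_validate(train: pd.DataFrame, spec: ModelSpec, k: int = 5) -> list[dict]:
    """Stratified k-fold metrics on the original training rows.

    Folds are formed from non-augmented rows only, the model is refit per
    fold, and weighted metrics are reported per fold.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    if "augmented" in train.columns:
        train = train[~train["augmented"].astype(bool)]
    _check_two_classes(train)
    X, y = _xy(train)
    minority = int(min(np.bincount(y)))
    if k > minority:
        raise ValidationError(f"k={k} exceeds the minority-class count {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
    folds = []
    for fold_idx, (tr, va) in enumerate(skf.split(X, y)):
        model = build_model(spec)
        model.fit(X.iloc[tr], y[tr])
        pred = model.predict(X.iloc[va])
        m = _metrics(y[va], pred)
        m["fold"] = fold_idx
        m["n"] = len(va)
        folds.append(m)
    return folds


def _augment_training(table: pd.DataFrame, train: pd.DataFrame, shifts) -> pd.DataFrame:
    """Augmented rows admissible for training: label row and feature-source
    row must both lie in the training portion."""
    base = table[~table["augmented"].astype(bool)] if "augmented" in table.columns else table
    aug = time_shift_augment(base, list(shifts))
    train_keys = set(zip(train["subject_id"], train["t"]))
    label_ok = [(s, t) in train_keys for s, t in zip(aug["subject_id"], aug["t"])]
    src_ok = [
        (s, t - k) in train_keys for s, t, k in zip(aug["subject_id"], aug["t"], aug["shift"])
    ]
    return aug[np.logical_and(label_ok, src_ok)]


def train_and_evaluate(
    table: pd.DataFrame,
    spec: ModelSpec,
    test_fraction: float = 0.2,
    k: int = 5,
    seed: int = 42,
    augment_shifts=DEFAULT_SHIFTS,
    run_cv: bool = False,
    model_path: str | None = None,
) -> EvalReport:
    """Train one model and evaluate it on a held-out stratified test set.

    The training portion is enlarged with time-shift-augmented rows
    (training-only by construction); the report carries weighted metrics,
    the (abnormal, normal)-oriented confusion matrix and, when ``run_cv``,
    per-fold cross-validation metrics.  ``model_path`` persists the fitted
    model with its feature manifest.
    """
    train, test = split_stratified(table, test_fraction, seed)
    fit_rows = train
    if augment_shifts:
        aug = _augment_training(table, train, augment_shifts)
        fit_rows = pd.concat([train, aug], ignore_index=True)
    per_fold = cross_validate(train, spec, k) if run_cv else []
    model = build_model(spec)
    X_fit, y_fit = _xy(fit_rows)
    model.fit(X_fit, y_fit)
    X_test, y_test = _xy(test)
    pred = model.predict(X_test)
    m = _metrics(y_test, pred)
    cm = confusion_matrix(y_test, pred, labels=[1, 0])
    report = EvalReport(
        model=spec.name,
        seed=spec.seed,
        confusion=cm,
        n_test=len(test),
        per_fold_metrics=per_fold,
        **m,
    )
    if model_path is not None:
        save_model(model_path, model, list(FEATURE_COLUMNS), spec)
    return report


def benchmark_all(
    table: pd.DataFrame,
    specs: list[ModelSpec] | None = None,
    test_fraction: float = 0.2,
    k: int = 5,
    seed: int = 42,
    augment_shifts=DEFAULT_SHIFTS,
) -> tuple[list[EvalReport], pd.DataFrame]:
    """Run every model under one split/seed and rank the results.

    A model that fails (e.g. the optional XGBoost library is absent) is
    reported with its error rather than aborting the benchmark.  Returns
    the reports and a comparison table with columns
    ``Models,Accuracy,Precision,Recall,f1-Score`` sorted in canonical
    model order.
    """
    if specs is None:
        specs = [ModelSpec(name=n, seed=seed) for n in MODEL_NAMES]
    reports: list[EvalReport] = []
    for spec in specs:
        try:
            reports.append(
                train_and_evaluate(
                    table, spec, test_fraction=test_fraction, k=k, seed=seed,
                    augment_shifts=augment_shifts,
                )
            )
        except ImportError as exc:
            warnings.warn(f"skipping {spec.name}: {exc}", stacklevel=2)
            reports.append(
                EvalReport(
                    model=spec.name, seed=spec.seed, accuracy=float("nan"),
                    precision=float("nan"), recall=float("nan"), f1=float("nan"),
                    confusion=np.zeros((2, 2), dtype=int), n_test=0, error=str(exc),
                )
            )
    rows = [
        {
            "Models": DISPLAY_NAMES[r.model],
            "Accuracy": round(r.accuracy, 2),
            "Precision": round(r.precision, 2),
            "Recall": round(r.recall, 2),
            "f1-Score": round(r.f1, 2),
        }
        for r in reports
        if r.error is None
    ]
    return reports, pd.DataFrame(rows, columns=["Models", "Accuracy", "Precision", "Recall", "f1-Score"])


def save_model(path: str, model, feature_names: list[str], spec: ModelSpec) -> None:
    """Persist a fitted model with a feature-name manifest and version tag."""
    joblib.dump(
        {
            "format_version": PERSIST_FORMAT_VERSION,
            "model": model,
            "feature_names": list(feature_names),
            "model_name": spec.name,
            "seed": spec.seed,
        },
        path,
    )


def load_model(path: str, expected_features: list[str] | None = None):
    """Load a persisted model, refusing feature-manifest mismatches.

    Returns ``(model, manifest)`` where the manifest holds the feature
    names, model name and seed recorded at save time.
    """
    payload = joblib.load(path)
    if payload.get("format_version") != PERSIST_FORMAT_VERSION:
        raise ValidationError(
            f"unsupported model file version {payload.get('format_version')!r}"
        )
    manifest = {k: payload[k] for k in ("feature_names", "model_name", "seed")}
    if expected_features is not None and list(expected_features) != list(payload["feature_names"]):
        raise ValidationError(
            "feature manifest mismatch: model was trained on "
            f"{payload['feature_names']}, pipeline provides {list(expected_features)}"
        )
    return payload["model"], manifest
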