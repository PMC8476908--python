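"""Position-error classification from radiomics feature matrices.

Pipeline stages, kept leakage-free by construction:

1. patient-level 80/20 split (32/8 at the study size of 40 patients) —
   all 27 samples of a patient fall on one side;
2. Pearson-correlation feature filter against the task label, fitted on
   training patients only;
3. leave-one-patient-out grid search over the model's hyperparameter
   grid, refit of the winner on the full training set;
4. prediction on the held-out patients.

Four model kinds are supported: linear discriminant classifier (LDC),
support vector machine (linear and RBF kernels in one grid), K-nearest
neighbours, and gradient-boosted trees (XGBoost).  Five tasks: type 1
(isocenter error > 3 mm), type 2 LR/SI/AP (per-axis > 3 mm), and the
8-way type 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, LeaveOneGroupOut
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

TASKS = ("type1", "type2_lr", "type2_si", "type2_ap", "type3")
MODEL_KINDS = ("ldc", "svm", "knn", "xgboost")
ML_CONFIGS = ("ml1", "ml2", "ml3")

#: columns of a feature matrix that are metadata, not features
META_COLUMNS = (
    "patient_id", "serial", "lr_mm", "si_mm", "ap_mm", "isocenter_mm",
    "type1", "type2_lr", "type2_si", "type2_ap", "type3",
)


@dataclass(frozen=True)
class GridSpec:
    """A model kind plus its hyperparameter search space."""

    model_kind: str
    grid: list[dict[str, list[Any]]]

    def __post_init__(self) -> None:
        if not self.grid or any(
            not cands for params in self.grid for cands in params.values()
        ):
            raise ValueError("candidate lists must be non-empty")


def default_grid(model_kind: str, task: str) -> GridSpec:
    """The study's hyperparameter search spaces.

    KNN: neighbours 1..10.  SVM: linear and RBF kernels, C in
    {0.01, 0.1, 1, 10}, gamma in {0.001, 0.01, 0.1, 1} (RBF only).
    LDC: solver in {svd, lsqr, eigen}.  XGBoost: max depth 3..10 with
    boosting rounds 10..100 step 10 (type 1/2) or 100..250 step 10
    (type 3).
    """
    model_kind = model_kind.lower()
    if model_kind == "knn":
        return GridSpec("knn", [{"clf__n_neighbors": list(range(1, 11))}])
    if model_kind == "svm":
        cs = [0.01, 0.1, 1, 10]
        return GridSpec(
            "svm",
            [
                {"clf__kernel": ["linear"], "clf__C": cs},
                {"clf__kernel": ["rbf"], "clf__C": cs,
                 "clf__gamma": [0.001, 0.01, 0.1, 1]},
            ],
        )
    if model_kind == "ldc":
        return GridSpec("ldc", [{"clf__solver": ["svd", "lsqr", "eigen"]}])
    if model_kind == "xgboost":
        rounds = (
            list(range(100, 251, 10)) if task == "type3" else list(range(10, 101, 10))
        )
        return GridSpec(
            "xgboost",
            [{"clf__n_estimators": rounds, "clf__max_depth": list(range(3, 11))}],
        )
    raise ValueError(f"unknown model kind {model_kind!r}")


def _make_estimator(model_kind: str, seed: int = 0) -> Pipeline:
    model_kind = model_kind.lower()
    if model_kind == "ldc":
        clf = LinearDiscriminantAnalysis()
    elif model_kind == "svm":
        clf = SVC(random_state=seed)
    elif model_kind == "knn":
        clf = KNeighborsClassifier()
    elif model_kind == "xgboost":
        clf = XGBClassifier(
            random_state=seed, n_jobs=1, verbosity=0, eval_metric="logloss"
        )
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if c not in META_COLUMNS]


def pearson_filter(
    x: pd.DataFrame, labels: Sequence[float], threshold: float = 0.1
) -> list[str]:
    """Columns whose |Pearson r| against the label coding reaches the cutoff.

    Zero-variance columns are always dropped (their correlation is
    undefined).  Raises when nothing survives.
    """
    if len(x) < 2:
        raise ValueError("need at least two samples")
    y = np.asarray(labels, dtype=np.float64)
    vals = x.to_numpy(dtype=np.float64)
    xc = vals - vals.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    keep = (sx > 0) & np.isfinite(r) & (np.abs(r) >= threshold)
    kept = [c for c, k in zip(x.columns, keep) if k]
    if not kept:
        raise ValueError(
            f"no feature reached |r| >= {threshold}; lower the threshold"
        )
    return kept


def split_by_patient(
    patient_ids: Sequence[str], seed: int, test_fraction: float = 0.2
) -> tuple[list[str], list[str]]:
    """Random patient-level split (32 train / 8 test at 40 patients)."""
    patients = sorted(set(patient_ids))
    if len(patients) < 2:
        raise ValueError("need at least two patients to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    n_test = max(1, int(round(len(patients) * test_fraction)))
    n_test = min(n_test, len(patients) - 1)
    test = sorted(patients[i] for i in order[:n_test])
    train = sorted(patients[i] for i in order[n_test:])
    return train, test


@dataclass
class TrainedModel:
    """A fitted classifier with its provenance."""

    model_kind: str
    task: str
    ml_config: str
    estimator: Pipeline
    selected_params: dict[str, Any]
    selected_features: list[str]
    classes: np.ndarray
    cv_accuracy: float

    def predict(self, x: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(x[self.selected_features].to_numpy())

    def predict_scores(self, x: pd.DataFrame) -> np.ndarray:
        """Per-class scores: probabilities when available, else a
        decision-function mapped to the (n_samples, n_classes) layout."""
        xv = x[self.selected_features].to_numpy()
        est = self.estimator
        if hasattr(est, "predict_proba"):
            try:
                return est.predict_proba(xv)
            except AttributeError:
                pass
        df = est.decision_function(xv)
        if df.ndim == 1:  # binary: score of the positive (second) class
            return np.column_stack([-df, df])
        return df


def tune_and_train(
    x_train: pd.DataFrame,
    y_train: Sequence[int],
    groups: Sequence[str],
    task: str,
    model_kind: str,
    grid: GridSpec | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Leave-one-patient-out grid search, then refit on all training data.

    The winning grid point is the one with the highest mean held-out-
    patient accuracy; ties go to the first-listed point.
    """
    y = np.asarray(y_train, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels are single-class; nothing to learn")
    grid = grid or default_grid(model_kind, task)
    est = _make_estimator(model_kind, seed)
    # xgboost needs 0-based contiguous class codes
    offset = int(y.min())
    search = GridSearchCV(
        est,
        grid.grid,
        scoring="accuracy",
        cv=LeaveOneGroupOut(),
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        search.fit(x_train.to_numpy(), y - offset, groups=np.asarray(groups))
    best = search.best_estimator_
    return TrainedModel(
        model_kind=model_kind,
        task=task,
        ml_config="",
        estimator=best,
        selected_params=dict(search.best_params_),
        selected_features=list(x_train.columns),
        classes=np.asarray(best.classes_) + offset,
        cv_accuracy=float(search.best_score_),
    )


@dataclass
class PredictionResult:
    """Held-out predictions plus everything needed for evaluation."""

    task: str
    ml_config: str
    model_kind: str
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # (n_samples, n_classes)
    classes: np.ndarray
    patient_ids: list[str] = field(default_factory=list)
    selected_features: list[str] = field(default_factory=list)
    selected_params: dict[str, Any] = field(default_factory=dict)


def run_experiment(
    features: pd.DataFrame,
    ml_config: str,
    task: str,
    model_kind: str,
    seed: int = 0,
    pearson_threshold: float = 0.1,
    grid: GridSpec | None = None,
    split: tuple[Sequence[str], Sequence[str]] | None = None,
) -> PredictionResult:
    """End-to-end: split, filter, tune, train, predict on held-out patients.

    ``features`` is a per-sample matrix (one row per patient x error
    position) carrying the metadata columns and the namespaced feature
    columns; ``ml_config`` selects which source maps' features enter.
    """
    from .radiomics_features import select_ml_columns

    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    cols = select_ml_columns(feature_columns(features), ml_config)
    if not cols:
        raise ValueError(f"no feature columns for config {ml_config!r}")
    if features[cols].isna().any().any():
        bad = features[cols].isna().any(axis=1)
        raise ValueError(f"missing feature values in rows {list(features.index[bad])}")

    if split is None:
        train_pat, test_pat = split_by_patient(features["patient_id"], seed)
    else:
        train_pat, test_pat = (list(split[0]), list(split[1]))
    in_train = features["patient_id"].isin(train_pat)
    train_df, test_df = features[in_train], features[~in_train]

    kept = pearson_filter(train_df[cols], train_df[task], pearson_threshold)
    model = tune_and_train(
        train_df[kept],
        train_df[task].to_numpy(),
        train_df["patient_id"].to_numpy(),
        task,
        model_kind,
        grid=grid,
        seed=seed,
    )
    model.ml_config = ml_config
    model.selected_features = kept

    offset = int(train_df[task].min())
    x_test = test_df[kept].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y_pred = model.estimator.predict(x_test) + offset
        if hasattr(model.estimator, "predict_proba"):
            try:
                scores = model.estimator.predict_proba(x_test)
            except AttributeError:
                scores = None
        else:
            scores = None
        if scores is None:
            df_scores = model.estimator.decision_function(x_test)
            scores = (
                np.column_stack([-df_scores, df_scores])
                if df_scores.ndim == 1
                else df_scores
            )
    return PredictionResult(
        task=task,
        ml_config=ml_config,
        model_kind=model_kind,
        y_true=test_df[task].to_numpy(dtype=np.int64),
        y_pred=np.asarray(y_pred, dtype=np.int64),
        scores=np.asarray(scores, dtype=np.float64),
        classes=model.classes,
        patient_ids=list(test_df["patient_id"]),
        selected_features=kept,
        selected_params=model.selected_params,
    )
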