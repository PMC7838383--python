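"""Normalization, splitting, classifiers, metrics, and the experiment grid.

The benchmark crosses two feature families (DWT statistics, Welch band
powers) with three feature sets (base features alone, base + the chosen
valence index, base + all eight preference indices) and six classifier
variants (feed-forward network under hinge / binary / categorical
cross-entropy losses, SVM, random forest with 500 trees, KNN).  Metrics are
accuracy and support-weighted precision/recall on a stratified ~20%
holdout; with weighted averaging, recall coincides with accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_score, recall_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from ._mlp import MLPBinaryClassifier
from .core_io import RunConfig, SchemaError, ShapeError, TrialEpoch, ValidationError
from .features_dwt import dwt_features_trial
from .features_psd import psd_features_trial
from .preference_indices import INDEX_NAMES, all_indices_trial

__all__ = [
    "FEATURE_FAMILIES",
    "FEATURE_SETS",
    "CLASSIFIERS",
    "FeatureMatrix",
    "ClassifierSpec",
    "EvalReport",
    "minmax_normalize",
    "holdout_split",
    "build_dnn_spec",
    "train_classifier",
    "evaluate_predictions",
    "build_feature_matrix",
    "run_experiment_grid",
    "grid_to_frame",
]

FEATURE_FAMILIES = ("dwt", "psd")
FEATURE_SETS = ("no_indices", "valence_only", "all_indices")
CLASSIFIERS = ("dnn_hinge", "dnn_binary_ce", "dnn_categorical_ce",
               "svm", "rf", "knn")

_LABEL_CODE = {"dislike": 0, "like": 1}


@dataclass
class FeatureMatrix:
    """Trials x named features with aligned like/dislike labels."""

    X: pd.DataFrame
    y: np.ndarray
    tag: str = ""

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if len(self.X) != len(self.y):
            raise ShapeError("feature rows and labels misaligned")
        if self.X.isna().any().any():
            raise ValidationError("feature matrix contains missing values")

    def __len__(self):
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class ClassifierSpec:
    algorithm: str  # one of CLASSIFIERS
    rf_trees: int = 500
    knn_k: int = 5
    svm_kernel: str = "rbf"
    svm_cost: float = 1.0
    dnn_learning_rate: float = 0.001
    dnn_dropout: float = 0.5
    dnn_epochs: int = 80
    dnn_batch_size: int = 32
    dnn_patience: int = 10
    dnn_start_epoch: int = 30
    dnn_regularization: str = "none"
    seed: int = 0

    @classmethod
    def from_config(cls, algorithm: str, config: RunConfig,
                    seed: int | None = None) -> "ClassifierSpec":
        c = config.classifiers
        return cls(algorithm=algorithm, rf_trees=c.rf_trees, knn_k=c.knn_k,
                   svm_kernel=c.svm_kernel, svm_cost=c.svm_cost,
                   dnn_learning_rate=c.dnn_learning_rate,
                   dnn_dropout=c.dnn_dropout, dnn_epochs=c.dnn_epochs,
                   dnn_batch_size=c.dnn_batch_size,
                   dnn_patience=c.dnn_patience,
                   dnn_start_epoch=c.dnn_start_epoch,
                   dnn_regularization=c.dnn_regularization,
                   seed=config.seed if seed is None else seed)


@dataclass
class EvalReport:
    accuracy: float
    precision: float  # support-weighted
    recall: float     # support-weighted (equals accuracy)
    per_class: dict[str, dict[str, float]]
    confusion: np.ndarray  # rows true, cols predicted, order (dislike, like)
    meta: dict = field(default_factory=dict)


def minmax_normalize(train: pd.DataFrame | np.ndarray,
                     apply_to: pd.DataFrame | np.ndarray | None = None):
    """Min-max scaling fitted on training columns only.

    x_scaled = (x - min) / (max - min); constant training columns map to 0.
    Held-out values outside the training range may leave [0, 1].
    Returns (scaled_train, scaled_apply_to, (min, max)).
    """
    tr = np.asarray(train, dtype=float)
    if tr.ndim != 2 or tr.shape[0] == 0:
        raise ValidationError("empty training set")
    lo = tr.min(axis=0)
    hi = tr.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    tr_scaled = (tr - lo) / safe
    tr_scaled[:, span == 0] = 0.0
    out = None
    if apply_to is not None:
        ap = np.asarray(apply_to, dtype=float)
        out = (ap - lo) / safe
        out[:, span == 0] = 0.0
    return tr_scaled, out, (lo, hi)


def holdout_split(matrix: FeatureMatrix, test_fraction: float = 0.2,
                  seed: int = 0) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified random holdout split, deterministic per seed."""
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    if len(set(matrix.y)) < 2:
        raise ValidationError("stratified split needs both classes present")
    idx_train, idx_test = train_test_split(
        np.arange(len(matrix)), test_size=test_fraction,
        random_state=seed, stratify=matrix.y)
    return (
        FeatureMatrix(matrix.X.iloc[idx_train].reset_index(drop=True),
                      matrix.y[idx_train], matrix.tag),
        FeatureMatrix(matrix.X.iloc[idx_test].reset_index(drop=True),
                      matrix.y[idx_test], matrix.tag),
    )


def build_dnn_spec(input_dim: int, loss: str) -> dict:
    """Layer plan: hidden widths halve from the input; 2-unit softmax head
    for cross-entropy losses, single linear margin unit for hinge."""
    hidden = MLPBinaryClassifier.hidden_sizes(input_dim)
    head = "linear_margin" if loss == "hinge" else "softmax"
    return {
        "input": input_dim,
        "hidden": hidden,
        "output": 1 if loss == "hinge" else 2,
        "activation": "relu",
        "head": head,
        "loss": loss,
    }


class _FittedModel:
    """Trained classifier bound to its feature schema."""

    def __init__(self, estimator, feature_names, scaler_bounds, is_mlp):
        self.estimator = estimator
        self.feature_names = list(feature_names)
        self.lo, self.hi = scaler_bounds
        self.is_mlp = is_mlp

    def _prepare(self, X: pd.DataFrame) -> np.ndarray:
        if list(X.columns) != self.feature_names:
            raise SchemaError("feature names differ from the training schema")
        span = self.hi - self.lo
        safe = np.where(span == 0, 1.0, span)
        scaled = (X.to_numpy(dtype=float) - self.lo) / safe
        scaled[:, span == 0] = 0.0
        return scaled

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scaled = self._prepare(X)
        codes = self.estimator.predict(scaled)
        inv = {v: k for k, v in _LABEL_CODE.items()}
        return np.array([inv[int(c)] for c in codes])


def train_classifier(spec: ClassifierSpec, train: FeatureMatrix) -> _FittedModel:
    """Normalize (train-fitted min-max) and fit the requested classifier."""
    if len(set(train.y)) < 2:
        raise ValidationError("training data must contain both classes")
    y = np.array([_LABEL_CODE[lab] for lab in train.y])
    X_scaled, _, bounds = minmax_normalize(train.X)
    algo = spec.algorithm
    if algo == "rf":
        est = RandomForestClassifier(n_estimators=spec.rf_trees,
                                     random_state=spec.seed, n_jobs=1)
    elif algo == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.knn_k)
    elif algo == "svm":
        est = SVC(kernel=spec.svm_kernel, C=spec.svm_cost,
                  random_state=spec.seed)
    elif algo.startswith("dnn_"):
        loss = algo[len("dnn_"):]
        est = MLPBinaryClassifier(
            loss=loss, learning_rate=spec.dnn_learning_rate,
            dropout=spec.dnn_dropout, epochs=spec.dnn_epochs,
            batch_size=spec.dnn_batch_size, patience=spec.dnn_patience,
            start_epoch=spec.dnn_start_epoch,
            regularization=spec.dnn_regularization, seed=spec.seed)
    else:
        raise ValidationError(f"unknown algorithm {spec.algorithm!r}")
    est.fit(X_scaled, y)
    return _FittedModel(est, train.feature_names, bounds,
                        is_mlp=algo.startswith("dnn_"))


def evaluate_predictions(truth: Sequence[str],
                         predicted: Sequence[str]) -> EvalReport:
    """Confusion counts, per-class and support-weighted precision/recall."""
    t = np.asarray(list(truth))
    p = np.asarray(list(predicted))
    if t.shape != p.shape or t.size == 0:
        raise ShapeError("truth and predictions must be equal-length, non-empty")
    classes = ["dislike", "like"]
    cm = confusion_matrix(t, p, labels=classes)
    accuracy = float(np.mean(t == p))
    precision = float(precision_score(t, p, labels=classes,
                                      average="weighted", zero_division=0))
    recall = float(recall_score(t, p, labels=classes,
                                average="weighted", zero_division=0))
    per_class = {}
    for i, c in enumerate(classes):
        tp = cm[i, i]
        per_class[c] = {
            "precision": float(tp / cm[:, i].sum()) if cm[:, i].sum() else 0.0,
            "recall": float(tp / cm[i].sum()) if cm[i].sum() else 0.0,
            "support": int(cm[i].sum()),
        }
    return EvalReport(accuracy=accuracy, precision=precision, recall=recall,
                      per_class=per_class, confusion=cm)


# ---------------------------------------------------------------------------
# Feature-matrix assembly and the experiment grid

def _base_features(epochs: Sequence[TrialEpoch], family: str,
                   config: RunConfig) -> pd.DataFrame:
    if family == "dwt":
        rows = [dwt_features_trial(ep, config.features) for ep in epochs]
    elif family == "psd":
        rows = [psd_features_trial(ep, config.features) for ep in epochs]
    else:
        raise ValidationError(f"unknown feature family {family!r}")
    return pd.DataFrame(rows)


def _index_features(epochs: Sequence[TrialEpoch],
                    config: RunConfig) -> pd.DataFrame:
    rows = [all_indices_trial(ep, config.features).as_dict() for ep in epochs]
    return pd.DataFrame(rows)


def build_feature_matrix(epochs: Sequence[TrialEpoch], family: str,
                         feature_set: str, config: RunConfig | None = None,
                         base: pd.DataFrame | None = None,
                         indices: pd.DataFrame | None = None,
                         valence_variant: str = "valence_v1") -> FeatureMatrix:
    """Assemble one grid cell's matrix: base family features plus,
    depending on the feature set, the valence index or all eight indices.

    Precomputed ``base``/``indices`` frames may be passed to avoid
    recomputing them across grid cells.
    """
    config = config or RunConfig()
    if feature_set not in FEATURE_SETS:
        raise ValidationError(f"unknown feature set {feature_set!r}")
    X = base if base is not None else _base_features(epochs, family, config)
    if feature_set != "no_indices":
        idx = indices if indices is not None else _index_features(epochs, config)
        cols = [valence_variant] if feature_set == "valence_only" else list(INDEX_NAMES)
        X = pd.concat([X.reset_index(drop=True),
                       idx[cols].reset_index(drop=True)], axis=1)
    y = np.array([ep.subjective_label for ep in epochs])
    return FeatureMatrix(X, y, tag=f"{family}:{feature_set}")


def run_experiment_grid(epochs: Sequence[TrialEpoch],
                        config: RunConfig | None = None,
                        families: Sequence[str] = FEATURE_FAMILIES,
                        feature_sets: Sequence[str] = FEATURE_SETS,
                        classifiers: Sequence[str] = CLASSIFIERS,
                        ) -> dict[tuple[str, str, str], EvalReport]:
    """Run the full benchmark: family x feature set x classifier.

    Returns a mapping (family, feature_set, classifier) -> EvalReport.
    Base and index features are computed once per family and shared.
    """
    config = config or RunConfig()
    indices = _index_features(epochs, config)
    reports: dict[tuple[str, str, str], EvalReport] = {}
    for family in families:
        base = _base_features(epochs, family, config)
        for fset in feature_sets:
            matrix = build_feature_matrix(epochs, family, fset, config,
                                          base=base, indices=indices)
            train, test = holdout_split(matrix, config.split_fraction,
                                        seed=config.seed)
            for algo in classifiers:
                spec = ClassifierSpec.from_config(algo, config)
                model = train_classifier(spec, train)
                report = evaluate_predictions(test.y, model.predict(test.X))
                report.meta = {"family": family, "feature_set": fset,
                               "classifier": algo, "seed": config.seed,
                               "n_train": len(train), "n_test": len(test)}
                reports[(family, fset, algo)] = report
    return reports


def grid_to_frame(reports: dict[tuple[str, str, str], EvalReport]) -> pd.DataFrame:
    """Long-format table of the grid results (one row per cell x metric)."""
    rows = []
    for (family, fset, algo), rep in reports.items():
        for metric in ("accuracy", "recall", "precision"):
            rows.append({
                "family": family, "feature_set": fset, "classifier": algo,
                "metric": metric, "value": getattr(rep, metric),
            })
    return pd.DataFrame(rows)
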