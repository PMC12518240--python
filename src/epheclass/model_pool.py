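"""Tuning and training of the base classifier pool, plus the DSEL carve-out.

Five classifier families span the pool: k-nearest neighbours, random forest,
SVM (with probability outputs), XGBoost and a multilayer perceptron. Each is
grid-tuned with stratified cross-validation scored by ROC AUC, refit on the
full training rows, and packaged together with the dynamic-selection
reference set (DSEL) — a stratified carve-out of labelled rows on which the
per-query competence of each model is later judged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .abundance_io import NEGATIVE_LABEL, POSITIVE_LABEL
from .errors import ValidationError
from .preprocessing import stratified_split

FAMILIES = ("knn", "random_forest", "svm", "xgboost", "mlp")


def default_grids() -> dict[str, dict[str, list]]:
    """Hyperparameter grids spanning each family's commonly tuned knobs."""
    return {
        "knn": {"n_neighbors": [3, 5, 7, 11], "weights": ["uniform", "distance"]},
        "random_forest": {
            "n_estimators": [200, 500],
            "max_depth": [None, 10],
            "min_samples_leaf": [1, 5],
        },
        "svm": {"kernel": ["rbf", "linear"], "C": [0.1, 1, 10], "gamma": ["scale"]},
        "xgboost": {"n_estimators": [200], "max_depth": [3, 6],
                    "learning_rate": [0.1, 0.3]},
        "mlp": {"hidden_layer_sizes": [(64,), (128, 64)],
                "alpha": [1e-4, 1e-3]},
    }


def small_grids() -> dict[str, dict[str, list]]:
    """One-point grids for quick runs (smoke tests, small synthetic studies)."""
    return {
        "knn": {"n_neighbors": [5]},
        "random_forest": {"n_estimators": [100]},
        "svm": {"kernel": ["rbf"], "C": [1]},
        "xgboost": {"n_estimators": [50], "max_depth": [3]},
        "mlp": {"hidden_layer_sizes": [(32,)], "alpha": [1e-4]},
    }


def _base_estimator(family: str, seed: int):
    if family == "knn":
        return KNeighborsClassifier()
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if family == "svm":
        # Platt-style calibration supplies the probability contract;
        # grid keys for this family are auto-prefixed with "estimator__"
        from sklearn.calibration import CalibratedClassifierCV
        return CalibratedClassifierCV(SVC(random_state=seed), cv=3)
    if family == "xgboost":
        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss")
    if family == "mlp":
        return MLPClassifier(random_state=seed, max_iter=500, early_stopping=True)
    raise ValidationError(f"unknown classifier family {family!r}")


@dataclass
class ClassifierSpec:
    """One family plus its candidate hyperparameter grid."""

    family: str
    grid: dict[str, list]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")
        if not self.grid:
            raise ValidationError("grid must be non-empty")
        if self.family == "svm":
            self.grid = {
                k if k.startswith("estimator__") else f"estimator__{k}": v
                for k, v in self.grid.items()
            }

    def estimator(self):
        return _base_estimator(self.family, self.seed)


@dataclass
class TunedModel:
    """A grid-tuning winner, refit on all rows it was tuned on."""

    family: str
    chosen_params: dict[str, Any]
    cv_auc_mean: float
    estimator: Any  # fitted, exposes predict_proba
    seed: int = 0

    def predict_proba_positive(self, X: np.ndarray) -> np.ndarray:
        """P(class = D) per row, using the estimator's classes_ ordering."""
        proba = self.estimator.predict_proba(X)
        classes = list(self.estimator.classes_)
        return proba[:, classes.index(_positive_class(classes))]


def _positive_class(classes: list) -> Any:
    # labels are either the canonical strings or 0/1 integers
    if POSITIVE_LABEL in classes:
        return POSITIVE_LABEL
    return max(classes)


def _encode_labels(y: np.ndarray) -> np.ndarray:
    """Map labels to integers (D -> 1, NotD -> 0); 0/1 pass through."""
    y = np.asarray(y)
    if y.dtype.kind in "iub":
        return y.astype(int)
    out = np.empty(y.shape, dtype=int)
    for i, v in enumerate(y.ravel()):
        if v == POSITIVE_LABEL or v == 1:
            out.flat[i] = 1
        elif v == NEGATIVE_LABEL or v == 0:
            out.flat[i] = 0
        else:
            raise ValidationError(f"unmappable label {v!r}")
    return out


def grid_tune(spec: ClassifierSpec, X: np.ndarray, y: np.ndarray,
              folds: int = 10, seed: int = 0) -> TunedModel:
    """Exhaustive grid search scored by mean fold ROC AUC.

    Ties are broken by grid order; the winner is refit on all provided rows.
    """
    X = np.asarray(X, dtype=float)
    y_enc = _encode_labels(y)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    class_counts = np.bincount(y_enc)
    if class_counts.size < 2 or class_counts.min() == 0:
        raise ValidationError("both classes required for tuning")
    if class_counts.min() < folds:
        raise ValidationError(
            f"smallest class ({class_counts.min()}) cannot fill {folds} stratified folds"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        spec.estimator(), spec.grid, scoring="roc_auc", cv=cv,
        n_jobs=1, refit=True, error_score="raise",
    )
    search.fit(X, y_enc)
    return TunedModel(
        family=spec.family,
        chosen_params=dict(search.best_params_),
        cv_auc_mean=float(search.best_score_),
        estimator=search.best_estimator_,
        seed=spec.seed,
    )


@dataclass
class ModelPool:
    """Trained base models plus the dynamic-selection reference set."""

    models: list[TunedModel]
    dsel_X: np.ndarray
    dsel_y: np.ndarray  # encoded 0/1, 1 = positive class D

    def __post_init__(self) -> None:
        if len(self.models) < 2:
            raise ValidationError("dynamic selection needs at least 2 models")
        self.dsel_X = np.asarray(self.dsel_X, dtype=float)
        self.dsel_y = np.asarray(self.dsel_y).astype(int)
        if set(np.unique(self.dsel_y)) != {0, 1}:
            raise ValidationError("DSEL must contain both classes")

    @property
    def n_models(self) -> int:
        return len(self.models)

    def predictions_on_dsel(self) -> np.ndarray:
        """Hard predictions of every model on DSEL, shape (n_models, n_dsel)."""
        return np.vstack([
            (m.predict_proba_positive(self.dsel_X) >= 0.5).astype(int)
            for m in self.models
        ])


def build_pool(tuned: list[TunedModel], X_train: np.ndarray, y_train: np.ndarray,
               dsel_fraction: float = 0.1, seed: int = 0) -> ModelPool:
    """Carve a stratified DSEL from the training rows and refit the models.

    The DSEL rows are held out untouched; each tuned model is refit (with its
    chosen hyperparameters) on the remaining rows only, so competence on DSEL
    is judged on data the models never saw.
    """
    if not 0 < dsel_fraction <= 0.5:
        raise ValidationError("dsel_fraction must be in (0, 0.5]")
    X_train = np.asarray(X_train, dtype=float)
    y_enc = _encode_labels(y_train)
    split = stratified_split(y_enc, 1.0 - dsel_fraction, seed)
    fit_idx, dsel_idx = split.train_idx, split.test_idx
    if len(np.unique(y_enc[dsel_idx])) < 2:
        raise ValidationError("DSEL carve-out lacks a class; increase dsel_fraction")
    refit: list[TunedModel] = []
    for m in tuned:
        est = clone(_base_estimator(m.family, m.seed))
        est.set_params(**m.chosen_params)
        est.fit(X_train[fit_idx], y_enc[fit_idx])
        refit.append(TunedModel(m.family, dict(m.chosen_params),
                                m.cv_auc_mean, est, m.seed))
    return ModelPool(refit, X_train[dsel_idx], y_enc[dsel_idx])
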