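"""Per-annotator classifiers and annotation learnability.

One classifier is trained per annotator on the shared six-feature table with
that annotator's own A–E labels.  Internal validation deliberately scores each
model against the annotations it learnt from: the resulting cross-validated
micro-F1 measures the *learnability* of that annotator's labelling — how
consistently their judgments follow from the recorded variables — rather than
accuracy against any ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, SchemaError, UnsupportedBackendError
from .simulate import FEATURES, AnnotatedPanel

TREE_BACKENDS = ("decision_tree", "random_forest")

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "decision_tree": {"max_depth": [3, 5, None], "min_samples_leaf": [1, 3]},
    "random_forest": {"n_estimators": [100], "max_depth": [5, None], "min_samples_leaf": [1, 3]},
    "logistic_regression": {"C": [0.1, 1.0, 10.0]},
}


@dataclass(frozen=True)
class ModelSpec:
    """Backend, hyperparameter grid and cross-validation settings."""

    backend: str = "decision_tree"
    hyperparameter_grid: dict | None = None
    cv_folds: int = 5
    class_weighting: str = "off"  # off | balanced
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in DEFAULT_GRIDS:
            raise ConfigurationError(
                f"unknown backend {self.backend!r}; choose from {sorted(DEFAULT_GRIDS)}"
            )
        if self.cv_folds < 2:
            raise ConfigurationError(f"cv_folds must be >= 2, got {self.cv_folds}")
        if self.class_weighting not in ("off", "balanced"):
            raise ConfigurationError("class_weighting must be 'off' or 'balanced'")
        if self.hyperparameter_grid is not None and not self.hyperparameter_grid:
            raise ConfigurationError("hyperparameter grid must be non-empty")

    @property
    def grid(self) -> dict:
        return self.hyperparameter_grid or DEFAULT_GRIDS[self.backend]


def _base_estimator(backend: str, class_weight, seed: int):
    if backend == "decision_tree":
        return DecisionTreeClassifier(class_weight=class_weight, random_state=seed)
    if backend == "random_forest":
        return RandomForestClassifier(class_weight=class_weight, random_state=seed)
    if backend == "logistic_regression":
        return LogisticRegression(class_weight=class_weight, max_iter=2000)
    raise ConfigurationError(f"unknown backend {backend!r}")


def _as_feature_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURES if c not in X.columns]
        if missing:
            raise SchemaError(f"missing feature column(s): {missing}")
        return X[FEATURES].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(FEATURES):
        raise SchemaError(f"expected {len(FEATURES)} feature columns, got shape {X.shape}")
    return X


class AnnotatorClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched classifier reproducing one annotator's labelling.

    Hyperparameters are chosen by cross-validated grid search maximising
    micro-F1, then the winning configuration is refit on all rows.  For a
    single-class (degenerate) label column a constant predictor is fitted
    instead and its cross-validated accuracy reported.

    Parameters
    ----------
    backend : {'decision_tree', 'random_forest', 'logistic_regression'}
    grid : hyperparameter grid; ``None`` selects a small documented default.
    cv_folds : folds for the model-selection cross-validation.
    class_weight : ``None`` or ``'balanced'``.
    random_state : seed controlling fold shuffling and backend tie-breaks.

    Attributes
    ----------
    best_estimator_ : the refit backend model.
    best_params_ : winning grid cell.
    cv_f1_micro_ : mean cross-validated micro-F1 of the winning cell
        (the learnability score when y is an annotator's own labels).
    fold_scores_ : per-fold micro-F1 of the winning cell.
    feature_importances_ : impurity-based importances (tree backends).
    """

    def __init__(self, backend="decision_tree", grid=None, cv_folds=5,
                 class_weight=None, random_state=0):
        self.backend = backend
        self.grid = grid
        self.cv_folds = cv_folds
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y, cv=None):
        """Fit with grid search; ``cv`` may be an explicit list of fold index
        pairs to share one row partition across several annotators."""
        X = _as_feature_array(X)
        y = np.asarray(y, dtype=object)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        spec_grid = self.grid or DEFAULT_GRIDS[self.backend]
        if not spec_grid:
            raise ConfigurationError("hyperparameter grid must be non-empty")
        self.classes_ = np.unique(y)

        if len(self.classes_) == 1:
            # Degenerate single-class annotator: constant model, CV accuracy 1.
            warnings.warn(
                f"single-class label column ({self.classes_[0]!r}); "
                "fitting a constant predictor",
                stacklevel=2,
            )
            self.best_estimator_ = DummyClassifier(
                strategy="constant", constant=self.classes_[0]
            ).fit(X, y)
            self.best_params_ = {}
            self.cv_f1_micro_ = 1.0
            self.fold_scores_ = np.ones(self.cv_folds)
            self.degenerate_ = True
            self.feature_importances_ = np.zeros(len(FEATURES))
            return self
        self.degenerate_ = False

        if cv is None:
            counts = pd.Series(y).value_counts()
            if counts.min() >= self.cv_folds:
                cv = StratifiedKFold(self.cv_folds, shuffle=True, random_state=self.random_state)
            else:
                warnings.warn(
                    "a class has fewer members than cv_folds; "
                    "falling back to unstratified folds",
                    stacklevel=2,
                )
                cv = KFold(self.cv_folds, shuffle=True, random_state=self.random_state)

        search = GridSearchCV(
            _base_estimator(self.backend, self.class_weight, self.random_state),
            spec_grid,
            scoring={"f1_micro": "f1_micro", "accuracy": "accuracy"},
            refit="f1_micro",
            cv=cv,
        )
        search.fit(X, y)
        res = search.cv_results_
        best = search.best_index_
        if isinstance(cv, int):
            folds = cv
        elif hasattr(cv, "n_splits"):
            folds = cv.n_splits
        else:
            folds = len(cv)
        f1 = np.array([res[f"split{k}_test_f1_micro"][best] for k in range(folds)])
        acc = np.array([res[f"split{k}_test_accuracy"][best] for k in range(folds)])
        # micro-F1 coincides with accuracy for single-label multiclass output
        if not np.allclose(f1, acc, atol=1e-12):
            raise AssertionError("micro-F1 != accuracy on a fold; evaluation is inconsistent")

        self.best_estimator_ = search.best_estimator_
        self.best_params_ = search.best_params_
        self.cv_f1_micro_ = float(search.best_score_)
        self.fold_scores_ = f1
        if self.backend in TREE_BACKENDS:
            self.feature_importances_ = self.best_estimator_.feature_importances_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "best_estimator_")
        return np.asarray(self.best_estimator_.predict(_as_feature_array(X)), dtype=object)

    def predict_ordinal(self, X) -> np.ndarray:
        """Predictions on the 1–5 ordinal scale (A=1 … E=5)."""
        from .consensus import to_ordinal

        return to_ordinal(self.predict(X))


@dataclass
class LearnabilityReport:
    """Per-annotator cross-validated micro-F1 against their own labels."""

    scores: dict[str, float]
    fold_scores: dict[str, np.ndarray]
    fold_indices: list[tuple[np.ndarray, np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        for aid, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"learnability score out of [0,1] for {aid}: {s}")

    @property
    def annotator_ids(self) -> list[str]:
        return list(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"annotator_id": list(self.scores), "cv_f1_micro": list(self.scores.values())}
        )


def _spec_to_estimator(spec: ModelSpec) -> AnnotatorClassifier:
    return AnnotatorClassifier(
        backend=spec.backend,
        grid=spec.hyperparameter_grid,
        cv_folds=spec.cv_folds,
        class_weight="balanced" if spec.class_weighting == "balanced" else None,
        random_state=spec.seed,
    )


def train_annotator_model(
    panel: AnnotatedPanel, annotator_id: str, spec: ModelSpec | None = None
) -> AnnotatorClassifier:
    """Train one annotator's classifier on the shared panel features."""
    spec = spec or ModelSpec()
    if annotator_id not in panel.labels.columns:
        raise KeyError(f"unknown annotator_id {annotator_id!r}")
    model = _spec_to_estimator(spec)
    model.fit(panel.features, panel.labels[annotator_id].to_numpy())
    model.annotator_id_ = annotator_id
    return model


def shared_folds(n_rows: int, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """One unstratified row partition reused across annotators for comparability."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr.copy(), te.copy()) for tr, te in kf.split(np.arange(n_rows))]


def assess_learnability(panel: AnnotatedPanel, spec: ModelSpec | None = None) -> LearnabilityReport:
    """Cross-validated micro-F1 of each annotator's model against their own labels.

    All annotators are scored on the same row partition so that scores are
    comparable across the panel; folds are therefore unstratified.
    """
    spec = spec or ModelSpec()
    folds = shared_folds(panel.n_records, spec.cv_folds, spec.seed)
    scores, fold_scores = {}, {}
    for aid in panel.annotator_ids:
        model = _spec_to_estimator(spec)
        model.fit(panel.features, panel.labels[aid].to_numpy(), cv=folds)
        scores[aid] = model.cv_f1_micro_
        fold_scores[aid] = model.fold_scores_
    return LearnabilityReport(scores=scores, fold_scores=fold_scores,
                              fold_indices=folds, seed=spec.seed)


def train_all_annotator_models(
    panel: AnnotatedPanel, spec: ModelSpec | None = None
) -> dict[str, AnnotatorClassifier]:
    """Fit one classifier per annotator; returns a mapping id -> fitted model."""
    return {aid: train_annotator_model(panel, aid, spec) for aid in panel.annotator_ids}


def predict_labels(model: AnnotatorClassifier, records) -> np.ndarray:
    """Predict A–E labels for records carrying the six feature columns."""
    if isinstance(records, pd.DataFrame) and len(records) == 0:
        return np.array([], dtype=object)
    return model.predict(records)


def feature_importance_table(models: dict[str, AnnotatorClassifier] | list) -> pd.DataFrame:
    """Annotator × feature impurity-importance matrix (tree backends only)."""
    if isinstance(models, dict):
        items = models.items()
    else:
        items = [(getattr(m, "annotator_id_", str(i)), m) for i, m in enumerate(models)]
    rows = {}
    for aid, model in items:
        if model.backend not in TREE_BACKENDS:
            raise UnsupportedBackendError(
                f"feature importances require a tree backend, {aid} uses {model.backend!r}"
            )
        imp = np.asarray(model.feature_importances_, dtype=float)
        if getattr(model, "degenerate_", False) or imp.sum() == 0:
            warnings.warn(f"degenerate importances for {aid} (constant model or no splits)")
        rows[aid] = imp
    return pd.DataFrame.from_dict(rows, orient="index", columns=FEATURES)
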