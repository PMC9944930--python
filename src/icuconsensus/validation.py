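"""External validation on discharge-vs-death tasks.

The five-point severity scale maps onto the binary discharge task through a
three-class grouping — CL1 = A (discharge within the hour), CL2 = B/C/D,
CL3 = E (death within the hour) — since ground truth exists only for the two
extremes.  Static evaluation grades last-hour predictions directly; temporal
evaluation combines five hourly predictions per patient into a weighted score
on [1, 5] (weights rise toward the outcome) and maps the score back to a
class through a named cut-off scheme.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, SchemaError
from .models import LearnabilityReport
from .simulate import FEATURES, ValidationSet

#: A–E to three-class grouping: CL1 = A, CL2 = B/C/D, CL3 = E
CLASS_GROUPING = {"A": "CL1", "B": "CL2", "C": "CL2", "D": "CL2", "E": "CL3"}

#: weights for hours-before-outcome 5,4,3,2,1 (sum to 1, rising toward outcome)
HOURLY_WEIGHTS = np.array([0.1, 0.1, 0.2, 0.3, 0.3])

_TOL = 1e-9

CUTOFF_SCHEMES = ("extreme", "neutral", "extreme2")


def group_labels(labels) -> np.ndarray:
    """Map A–E labels to CL1/CL2/CL3."""
    arr = np.asarray(labels, dtype=object)
    try:
        return np.array([CLASS_GROUPING[l] for l in arr], dtype=object)
    except KeyError as err:
        raise SchemaError(f"label outside A-E alphabet: {err.args[0]!r}") from None


def ground_truth_class(outcome: str) -> str:
    """Discharge status to its extreme severity class (alive→CL1, died→CL3)."""
    mapping = {"discharged_alive": "CL1", "died": "CL3"}
    if outcome not in mapping:
        raise SchemaError(f"unknown outcome {outcome!r}; expected discharged_alive or died")
    return mapping[outcome]


def temporal_weighted_score(hourly, weights=HOURLY_WEIGHTS) -> float:
    """Weighted sum of five hourly scores (ordered hour 5 → hour 1).

    With weights summing to 1 this is the weighted mean, so the result stays
    in [1, 5].
    """
    hourly = np.asarray(hourly, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if hourly.shape != (5,) or weights.shape != (5,):
        raise ValueError(f"expected 5 hourly values and 5 weights, got {hourly.shape}")
    if np.any((hourly < 1 - _TOL) | (hourly > 5 + _TOL)):
        raise ValueError(f"hourly values must lie in [1,5], got {hourly}")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return float(hourly @ weights)


def map_score(score: float, scheme: str = "extreme", tol: float = _TOL) -> str:
    """Map a [1, 5] score to CL1/CL2/CL3 under a named cut-off scheme.

    * ``extreme``:  CL1 = 1, CL2 = >1–4, CL3 = >4
    * ``neutral``:  CL1 = ≤3, CL2 = >3–<4, CL3 = ≥4
    * ``extreme2``: CL1 = ≤2, CL2 = >2–<4, CL3 = ≥4

    Boundaries follow the printed inequalities with a floating tolerance.
    """
    if not 1 - tol <= score <= 5 + tol:
        raise ValueError(f"score must lie in [1,5], got {score}")
    if scheme == "extreme":
        if score <= 1 + tol:
            return "CL1"
        return "CL2" if score <= 4 + tol else "CL3"
    if scheme == "neutral":
        if score >= 4 - tol:
            return "CL3"
        return "CL1" if score <= 3 + tol else "CL2"
    if scheme == "extreme2":
        if score >= 4 - tol:
            return "CL3"
        return "CL1" if score <= 2 + tol else "CL2"
    raise ConfigurationError(f"unknown cut-off scheme {scheme!r}; choose from {CUTOFF_SCHEMES}")


class ValidationResult:
    """Scores of one model on one validation set."""

    def __init__(self, model_id, micro_f1, correct_alive, correct_dead,
                 n_alive, n_died, layout, scheme=None):
        if not 0.0 <= micro_f1 <= 1.0:
            raise ValueError(f"micro_f1 out of [0,1]: {micro_f1}")
        if correct_alive > n_alive or correct_dead > n_died:
            raise ValueError("correct counts exceed class sizes")
        self.model_id = model_id
        self.micro_f1 = float(micro_f1)
        self.correct_alive = int(correct_alive)
        self.correct_dead = int(correct_dead)
        self.n_alive = int(n_alive)
        self.n_died = int(n_died)
        self.layout = layout
        self.scheme = scheme

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"ValidationResult({self.model_id!r}, micro_f1={self.micro_f1:.3f}, "
            f"alive={self.correct_alive}/{self.n_alive}, "
            f"dead={self.correct_dead}/{self.n_died}, layout={self.layout!r})"
        )


def results_table(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "model_id": [r.model_id for r in results],
            "micro_f1": [r.micro_f1 for r in results],
            "correct_alive": [r.correct_alive for r in results],
            "correct_dead": [r.correct_dead for r in results],
            "n_alive": [r.n_alive for r in results],
            "n_died": [r.n_died for r in results],
            "layout": [r.layout for r in results],
            "scheme": [r.scheme or "" for r in results],
        }
    )


def _score_result(model_id, pred_class, truth_class, outcomes, layout, scheme) -> ValidationResult:
    pred_class = np.asarray(pred_class, dtype=object)
    truth_class = np.asarray(truth_class, dtype=object)
    hit = pred_class == truth_class
    alive = np.asarray(outcomes, dtype=object) == "discharged_alive"
    return ValidationResult(
        model_id=model_id,
        micro_f1=float(hit.mean()),
        correct_alive=int(hit[alive].sum()),
        correct_dead=int(hit[~alive].sum()),
        n_alive=int(alive.sum()),
        n_died=int((~alive).sum()),
        layout=layout,
        scheme=scheme,
    )


def evaluate_static(model, vset: ValidationSet, model_id: str | None = None,
                    scheme: str = "neutral") -> ValidationResult:
    """Score a model on a static (last-hour) validation set.

    Categorical models are graded through the A–E → CL grouping; consensus
    models producing real-valued confidences (``predict_confidence``) are
    graded through the ``scheme`` cut-offs.  Micro-F1 is computed on the
    grouped three-class task, so CL2 predictions count against both outcome
    scenarios.
    """
    if vset.layout != "static":
        raise ConfigurationError(f"expected a static layout, got {vset.layout!r}")
    X = vset.feature_table()
    if hasattr(model, "predict_confidence"):
        scores = model.predict_confidence(X)
        pred_class = np.array([map_score(s, scheme) for s in scores], dtype=object)
        used_scheme = scheme
    else:
        pred_class = group_labels(model.predict(X))
        used_scheme = None
    outcomes = vset.records["outcome"].to_numpy(object)
    truth = np.array([ground_truth_class(o) for o in outcomes], dtype=object)
    mid = model_id or getattr(model, "annotator_id_", None) or getattr(model, "kind", "model")
    return _score_result(mid, pred_class, truth, outcomes, "static", used_scheme)


def evaluate_temporal(model, vset: ValidationSet, scheme: str = "neutral",
                      model_id: str | None = None,
                      weights=HOURLY_WEIGHTS) -> ValidationResult:
    """Score a model on a temporal (5-hour trajectory) validation set.

    Per patient, the five hourly ordinal predictions (or fuzzy confidences)
    are combined by :func:`temporal_weighted_score` and mapped to a class
    under ``scheme``.
    """
    if vset.layout != "temporal":
        raise ConfigurationError(f"expected a temporal layout, got {vset.layout!r}")
    recs = vset.records
    bad = recs.groupby("patient_id").size()
    bad = bad[bad != 5]
    if len(bad):
        raise ConfigurationError(f"patient(s) without exactly 5 records: {list(bad.index)[:5]}")

    X = recs[FEATURES]
    if hasattr(model, "predict_confidence"):
        hourly = model.predict_confidence(X)
    else:
        hourly = model.predict_ordinal(X)
    work = recs[["patient_id", "hours_before_outcome", "outcome"]].copy()
    work["score"] = hourly

    pred_class, truth, outcomes = [], [], []
    for pid, grp in work.groupby("patient_id", sort=True):
        grp = grp.sort_values("hours_before_outcome", ascending=False)
        s = temporal_weighted_score(grp["score"].to_numpy(), weights)
        pred_class.append(map_score(s, scheme))
        outcome = grp["outcome"].iloc[0]
        outcomes.append(outcome)
        truth.append(ground_truth_class(outcome))
    mid = model_id or getattr(model, "annotator_id_", None) or getattr(model, "kind", "model")
    return _score_result(mid, pred_class, truth, outcomes, "temporal", scheme)


def internal_external_correlation(report: LearnabilityReport,
                                  results: list[ValidationResult]) -> float:
    """Pearson r between internal learnability and external micro-F1."""
    ext = {r.model_id: r.micro_f1 for r in results}
    ids = [aid for aid in report.annotator_ids if aid in ext]
    if set(report.annotator_ids) - set(ext):
        missing = sorted(set(report.annotator_ids) - set(ext))
        raise ValueError(f"no external result for annotator(s): {missing}")
    if len(ids) < 3:
        raise ValueError("correlation needs at least 3 matched annotators")
    internal = [report.scores[a] for a in ids]
    external = [ext[a] for a in ids]
    return float(stats.pearsonr(internal, external)[0])


#: feature columns of the hourly discharge-status model, hour 5 → hour 1
HOUR_COLUMNS = ["hour_5", "hour_4", "hour_3", "hour_2", "hour_1"]


def hourly_outcome_model(hourly_labels: pd.DataFrame, outcomes,
                         backend: str = "logistic_regression", seed: int = 0):
    """Fit the hourly discharge-status model; see :class:`HourlyOutcomeModel`.

    Parameters
    ----------
    hourly_labels : one row per patient with columns hour_5 … hour_1 holding
        ordinal (1–5) severity predictions.
    outcomes : per-patient discharge status.

    Returns
    -------
    dict with the fitted ``model``, ``cv_f1_micro``, and for the logistic
    backend a per-hour ``odds_ratios`` Series (exp of the died-class
    coefficients).
    """
    if backend not in ("decision_tree", "logistic_regression"):
        raise ConfigurationError(
            f"backend must be decision_tree or logistic_regression, got {backend!r}"
        )
    X = np.asarray(hourly_labels[HOUR_COLUMNS]
                   if isinstance(hourly_labels, pd.DataFrame) else hourly_labels, dtype=float)
    y = np.asarray(outcomes, dtype=object)
    if len(X) < 20:
        raise ValueError("need at least 20 patients")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcomes must be present")

    if backend == "logistic_regression":
        base = LogisticRegression(max_iter=2000)
        grid = {"C": [0.1, 1.0, 10.0]}
    else:
        base = DecisionTreeClassifier(random_state=seed)
        grid = {"max_depth": [2, 3, 5, None]}
    cv = StratifiedKFold(5, shuffle=True, random_state=seed)
    search = GridSearchCV(base, grid, scoring="f1_micro", cv=cv)
    search.fit(X, y)

    out = {"model": search.best_estimator_, "cv_f1_micro": float(search.best_score_),
           "odds_ratios": None}
    if backend == "logistic_regression":
        est = search.best_estimator_
        coefs = est.coef_[0]
        # orient so odds ratios refer to the risk of death
        if list(est.classes_).index("died") == 0:
            coefs = -coefs
        out["odds_ratios"] = pd.Series(np.exp(coefs), index=HOUR_COLUMNS)
    return out


def build_hourly_label_table(model, vset: ValidationSet) -> tuple[pd.DataFrame, pd.Series]:
    """Pivot a temporal validation set into per-patient hourly ordinal predictions."""
    if vset.layout != "temporal":
        raise ConfigurationError("hourly label table requires a temporal validation set")
    recs = vset.records
    if hasattr(model, "predict_confidence"):
        values = model.predict_confidence(recs[FEATURES])
    else:
        values = model.predict_ordinal(recs[FEATURES])
    work = recs[["patient_id", "hours_before_outcome"]].copy()
    work["value"] = values
    wide = work.pivot(index="patient_id", columns="hours_before_outcome", values="value")
    wide = wide[[5, 4, 3, 2, 1]]
    wide.columns = HOUR_COLUMNS
    return wide, vset.outcomes.loc[wide.index]
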