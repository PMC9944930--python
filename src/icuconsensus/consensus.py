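"""Consensus constructions over multi-annotator labels and models.

Four consensus schemes are provided:

* **MV** — majority vote over all annotators' label columns; the fused labels
  train a single "consensus annotator" classifier.
* **TMV** — majority vote restricted to annotators whose labelling is
  *learnable* (internal cross-validated micro-F1 strictly above a threshold,
  0.7 by default).
* **FC** — fuzzy consensus: member models' A–E predictions are read on the
  1–5 ordinal scale and averaged per record, excluding exact midpoint (3)
  outputs as "uncertain"; the result is a real-valued confidence in [1, 5].
* **TFC** — fuzzy consensus over the learnable members only.

MV/TMV fuse *training labels*; FC/TFC fuse *predictions* at inference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError
from .models import AnnotatorClassifier, LearnabilityReport, ModelSpec, _spec_to_estimator
from .simulate import LABELS, AnnotatedPanel

LABEL_TO_ORDINAL = {lab: i + 1 for i, lab in enumerate(LABELS)}
ORDINAL_TO_LABEL = {v: k for k, v in LABEL_TO_ORDINAL.items()}


def to_ordinal(labels) -> np.ndarray:
    """Map A–E labels to the 1–5 ordinal scale."""
    return np.array([LABEL_TO_ORDINAL[l] for l in np.asarray(labels, dtype=object)], dtype=float)


def to_label(ordinals) -> np.ndarray:
    """Map 1–5 ordinals back to A–E labels."""
    return np.array([ORDINAL_TO_LABEL[int(v)] for v in np.asarray(ordinals)], dtype=object)


def majority_vote(labels: pd.DataFrame, tie_rule: str = "most_severe", seed: int = 0) -> pd.Series:
    """Per-item modal label across annotator columns.

    Ties between modal labels are broken by ``tie_rule``: ``most_severe``
    (highest ordinal; clinically conservative default), ``least_severe``, or
    ``random`` (seeded).
    """
    labels = pd.DataFrame(labels)
    if labels.shape[1] < 2:
        raise ConfigurationError("majority vote needs at least 2 annotator columns")
    if labels.isna().any().any():
        raise ConfigurationError("majority vote requires a complete panel")
    if tie_rule not in ("most_severe", "least_severe", "random"):
        raise ConfigurationError(f"unknown tie_rule {tie_rule!r}")
    rng = np.random.default_rng(seed)

    out = []
    for _, row in labels.iterrows():
        counts = row.value_counts()
        modes = counts.index[counts == counts.max()].tolist()
        if len(modes) == 1:
            out.append(modes[0])
        elif tie_rule == "most_severe":
            out.append(max(modes, key=LABEL_TO_ORDINAL.get))
        elif tie_rule == "least_severe":
            out.append(min(modes, key=LABEL_TO_ORDINAL.get))
        else:
            out.append(rng.choice(sorted(modes)))
    return pd.Series(out, index=labels.index, dtype=object)


def select_top_annotators(report: LearnabilityReport, threshold: float = 0.7) -> list[str]:
    """Annotators whose learnability is strictly above ``threshold``."""
    if not report.scores:
        raise ConfigurationError("empty learnability report")
    chosen = [aid for aid, s in report.scores.items() if s > threshold]
    if not chosen:
        raise ConfigurationError(
            f"no annotator has learnability > {threshold}; lower the threshold "
            f"(scores range {min(report.scores.values()):.3f}"
            f"-{max(report.scores.values()):.3f})"
        )
    return chosen


def build_consensus_training_labels(
    panel: AnnotatedPanel,
    kind: str,
    report: LearnabilityReport | None = None,
    threshold: float = 0.7,
    tie_rule: str = "most_severe",
    seed: int = 0,
) -> pd.Series:
    """Fused label column for training a consensus classifier (MV or TMV)."""
    if kind not in ("MV", "TMV"):
        raise ConfigurationError(f"kind must be 'MV' or 'TMV', got {kind!r}")
    cols = panel.labels
    if kind == "TMV":
        if report is None:
            raise ConfigurationError("TMV requires a learnability report")
        members = select_top_annotators(report, threshold)
        if len(members) == 1:
            return cols[members[0]].copy()
        cols = cols[members]
    return majority_vote(cols, tie_rule=tie_rule, seed=seed)


class ConsensusClassifier(BaseEstimator, ClassifierMixin):
    """Classifier trained on majority-vote (MV) or learnability-gated (TMV) labels.

    ``fit`` takes the annotated panel (and, for TMV, a learnability report),
    fuses a training-label column, and fits an :class:`AnnotatorClassifier`
    on the shared features.

    Attributes
    ----------
    members_ : annotator ids whose labels entered the vote.
    training_labels_ : the fused label column.
    model_ : the fitted underlying classifier.
    """

    def __init__(self, kind="MV", threshold=0.7, tie_rule="most_severe",
                 model_spec: ModelSpec | None = None):
        self.kind = kind
        self.threshold = threshold
        self.tie_rule = tie_rule
        self.model_spec = model_spec

    def fit(self, panel: AnnotatedPanel, report: LearnabilityReport | None = None):
        spec = self.model_spec or ModelSpec()
        self.members_ = (
            select_top_annotators(report, self.threshold)
            if self.kind == "TMV"
            else panel.annotator_ids
        )
        self.training_labels_ = build_consensus_training_labels(
            panel, self.kind, report, self.threshold, self.tie_rule, seed=spec.seed
        )
        self.model_ = _spec_to_estimator(spec)
        self.model_.fit(panel.features, self.training_labels_.to_numpy())
        self.backend = self.model_.backend
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(X)

    def predict_ordinal(self, X) -> np.ndarray:
        return to_ordinal(self.predict(X))


def fuzzy_average(outputs) -> float:
    """Average ordinal outputs on the 1–5 scale, excluding midpoint (3) values.

    The midpoint sits at the centre of the discharge(1)–death(5) confidence
    scale and is read as "uncertain", so it carries no weight; if every
    output is the midpoint the consensus is itself uncertain and 3.0 is
    returned.
    """
    arr = np.asarray(outputs, dtype=float)
    if arr.size == 0:
        raise ValueError("fuzzy_average requires at least one output")
    if np.any((arr < 1) | (arr > 5)):
        raise ValueError(f"ordinal outputs must lie in [1,5], got {arr}")
    kept = arr[arr != 3]
    if kept.size == 0:
        return 3.0
    return float(kept.mean())


class FuzzyConsensus(BaseEstimator):
    """Prediction-fusing consensus over fitted annotator models (FC / TFC).

    Members' A–E predictions are mapped to 1–5 and combined per record with
    :func:`fuzzy_average`; ``predict_confidence`` returns real-valued scores
    in [1, 5] consumed directly by the temporal weighting machinery (they are
    deliberately not rounded back to categories).
    """

    def __init__(self, models: dict[str, AnnotatorClassifier], member_ids=None):
        if not models:
            raise ConfigurationError("FuzzyConsensus requires at least one fitted model")
        self.models = dict(models)
        if member_ids is None:
            member_ids = list(self.models)
        missing = set(member_ids) - set(self.models)
        if missing:
            raise ConfigurationError(f"member ids without models: {sorted(missing)}")
        if not member_ids:
            raise ConfigurationError("empty member set")
        self.member_ids = list(member_ids)

    @classmethod
    def top(cls, models: dict[str, AnnotatorClassifier], report: LearnabilityReport,
            threshold: float = 0.7) -> "FuzzyConsensus":
        """TFC: restrict members to learnable annotators."""
        return cls(models, member_ids=select_top_annotators(report, threshold))

    def predict_confidence(self, records) -> np.ndarray:
        preds = np.column_stack(
            [self.models[aid].predict_ordinal(records) for aid in self.member_ids]
        )
        return np.array([fuzzy_average(row) for row in preds])


def fuzzy_consensus_predict(
    models: dict[str, AnnotatorClassifier],
    records,
    member_set: str = "all",
    report: LearnabilityReport | None = None,
    threshold: float = 0.7,
) -> np.ndarray:
    """Per-record fuzzy-consensus confidences from all ('FC') or top ('TFC') members."""
    if member_set == "all":
        fc = FuzzyConsensus(models)
    elif member_set == "top":
        if report is None:
            raise ConfigurationError("member_set='top' requires a learnability report")
        fc = FuzzyConsensus.top(models, report, threshold)
    else:
        raise ConfigurationError(f"member_set must be 'all' or 'top', got {member_set!r}")
    return fc.predict_confidence(records)
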