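import numpy as np
import pandas as pd
import pytest

from icuconsensus import (
    AnnotatedPanel,
    ModelSpec,
    default_profiles,
    generate_annotated_panel,
    generate_cohort,
    make_validation_sets,
)
from icuconsensus.simulate import FEATURES, features_from_severity, severity_band


@pytest.fixture(scope="session")
def default_panel():
    """60-record panel under the default 11-annotator mixed-quality regime."""
    return generate_annotated_panel(60, default_profiles(0), seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(400, seed=7)


@pytest.fixture(scope="session")
def static_vset(small_cohort):
    return make_validation_sets(small_cohort, 50, 50, "static", seed=2)


@pytest.fixture(scope="session")
def temporal_vset(small_cohort):
    return make_validation_sets(small_cohort, 50, 50, "temporal", seed=2)


@pytest.fixture
def fast_spec():
    """Small decision-tree spec to keep grid searches quick."""
    return ModelSpec(backend="decision_tree", hyperparameter_grid={"max_depth": [3, None]},
                     cv_folds=5, seed=0)


def rule_panel(n=120, seed=0, feature="fio2", annotators=("R1", "R2")):
    """Panel whose labels are a noise-free threshold function of latent severity.

    The generating banding rule is the oracle for learnability and
    feature-importance checks.
    """
    rng = np.random.default_rng(seed)
    z = rng.uniform(0, 1, n)
    feats = features_from_severity(z, rng)
    if feature is not None:
        # make the label a pure threshold function of one observed feature
        qs = np.quantile(feats[feature], [0.2, 0.4, 0.6, 0.8])
        labels = severity_band(feats[feature], qs)
    else:
        labels = severity_band(z)
    lab = pd.DataFrame({a: labels for a in annotators}, index=feats.index)
    return AnnotatedPanel(features=feats, labels=lab), labels


@pytest.fixture
def threshold_panel():
    return rule_panel()


class ConstantModel:
    """Predicts one fixed A-E label everywhere (test double)."""

    backend = "decision_tree"

    def __init__(self, label):
        self.label = label
        self.annotator_id_ = f"const_{label}"

    def predict(self, X):
        return np.array([self.label] * len(X), dtype=object)

    def predict_ordinal(self, X):
        from icuconsensus.consensus import to_ordinal

        return to_ordinal(self.predict(X))


class OracleModel:
    """Predicts A for discharged-alive rows and E for died rows (needs outcome)."""

    def __init__(self, records):
        self._lookup = records["outcome"].map(
            {"discharged_alive": "A", "died": "E"}
        ).to_numpy(object)
        self._features = records[FEATURES].reset_index(drop=True)

    def predict(self, X):
        assert len(X) == len(self._lookup)
        return self._lookup

    def predict_ordinal(self, X):
        from icuconsensus.consensus import to_ordinal

        return to_ordinal(self.predict(X))
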