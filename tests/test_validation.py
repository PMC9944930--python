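import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icuconsensus import (
    ConfigurationError,
    HOURLY_WEIGHTS,
    SchemaError,
    build_hourly_label_table,
    evaluate_static,
    evaluate_temporal,
    ground_truth_class,
    group_labels,
    hourly_outcome_model,
    internal_external_correlation,
    map_score,
    temporal_weighted_score,
)
from icuconsensus.models import LearnabilityReport
from icuconsensus.validation import ValidationResult
from conftest import ConstantModel, OracleModel


def make_report(scores):
    return LearnabilityReport(
        scores=scores, fold_scores={k: np.array([v]) for k, v in scores.items()},
        fold_indices=[], seed=0,
    )


def result(mid, f1, ca, cd, na=50, nd=50):
    return ValidationResult(mid, f1, ca, cd, na, nd, "static")


class TestGrouping:
    def test_ground_truth_mapping(self):
        assert ground_truth_class("discharged_alive") == "CL1"
        assert ground_truth_class("died") == "CL3"

    def test_unknown_outcome_rejected(self):
        with pytest.raises(SchemaError):
            ground_truth_class("transferred")

    def test_grouping_total_over_alphabet(self):
        assert list(group_labels(list("ABCDE"))) == ["CL1", "CL2", "CL2", "CL2", "CL3"]

    def test_unknown_label_rejected(self):
        with pytest.raises(SchemaError):
            group_labels(["F"])


class TestEvaluateStatic:
    def test_constant_a_predictor_bookkeeping(self, static_vset):
        res = evaluate_static(ConstantModel("A"), static_vset)
        assert res.correct_alive == 50
        assert res.correct_dead == 0
        assert res.micro_f1 == pytest.approx(0.5)

    def test_constant_c_predictor_never_correct(self, static_vset):
        res = evaluate_static(ConstantModel("C"), static_vset)
        assert res.micro_f1 == 0.0
        assert res.correct_alive == res.correct_dead == 0

    def test_oracle_predictor_perfect(self, static_vset):
        res = evaluate_static(OracleModel(static_vset.records), static_vset)
        assert res.micro_f1 == 1.0
        assert res.correct_alive == 50 and res.correct_dead == 50

    def test_layout_mismatch_rejected(self, temporal_vset):
        with pytest.raises(ConfigurationError):
            evaluate_static(ConstantModel("A"), temporal_vset)

    def test_count_conservation(self, static_vset):
        for label in "ABCDE":
            r = evaluate_static(ConstantModel(label), static_vset)
            assert r.correct_alive + r.correct_dead <= 100


class TestTemporalWeightedScore:
    def test_unanimity_bounds(self):
        assert temporal_weighted_score([1, 1, 1, 1, 1]) == 1.0
        assert temporal_weighted_score([5, 5, 5, 5, 5]) == 5.0

    def test_dot_product_oracle(self):
        assert temporal_weighted_score([1, 2, 3, 4, 5]) == pytest.approx(3.6, abs=1e-12)

    def test_weights_definition(self):
        np.testing.assert_allclose(HOURLY_WEIGHTS, [0.1, 0.1, 0.2, 0.3, 0.3])
        assert HOURLY_WEIGHTS.sum() == pytest.approx(1.0)
        assert (np.diff(HOURLY_WEIGHTS) >= 0).all()

    def test_arity_and_range_errors(self):
        with pytest.raises(ValueError):
            temporal_weighted_score([1, 2, 3])
        with pytest.raises(ValueError):
            temporal_weighted_score([0, 2, 3, 4, 5])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1, max_value=5), min_size=5, max_size=5),
        st.integers(min_value=0, max_value=4),
        st.floats(min_value=0.01, max_value=1.0),
    )
    def test_monotone_in_each_hour(self, hourly, idx, bump):
        raised = list(hourly)
        raised[idx] = min(5.0, raised[idx] + bump)
        assert temporal_weighted_score(raised) >= temporal_weighted_score(hourly) - 1e-12


class TestMapScore:
    @pytest.mark.parametrize(
        "score,scheme,expected",
        [
            (3.6, "extreme", "CL2"), (3.6, "neutral", "CL2"),
            (4.0, "neutral", "CL3"), (4.0, "extreme", "CL2"),
            (1.0, "extreme", "CL1"), (3.0, "neutral", "CL1"),
            (1.5, "extreme", "CL2"), (4.2, "extreme", "CL3"),
            (2.0, "extreme2", "CL1"), (3.5, "extreme2", "CL2"), (4.0, "extreme2", "CL3"),
        ],
    )
    def test_printed_interval_rules(self, score, scheme, expected):
        assert map_score(score, scheme) == expected

    def test_out_of_range_and_unknown_scheme(self):
        with pytest.raises(ValueError):
            map_score(5.2, "extreme")
        with pytest.raises(ConfigurationError):
            map_score(3.0, "weird")

    @pytest.mark.parametrize("scheme", ["extreme", "neutral", "extreme2"])
    def test_every_score_maps_to_exactly_one_class(self, scheme):
        for s in np.linspace(1, 5, 2001):
            assert map_score(float(s), scheme) in {"CL1", "CL2", "CL3"}


class TestEvaluateTemporal:
    def test_oracle_hourly_predictions_perfect_under_any_scheme(self, temporal_vset):
        oracle = OracleModel(temporal_vset.records)
        for scheme in ("extreme", "neutral", "extreme2"):
            assert evaluate_temporal(oracle, temporal_vset, scheme).micro_f1 == 1.0

    def test_all_midpoint_predictions_favour_discharge_under_neutral(self, temporal_vset):
        res = evaluate_temporal(ConstantModel("C"), temporal_vset, "neutral")
        assert res.correct_alive == res.n_alive
        assert res.correct_dead == 0

    def test_all_midpoint_predictions_are_cl2_under_extreme(self, temporal_vset):
        res = evaluate_temporal(ConstantModel("C"), temporal_vset, "extreme")
        assert res.correct_alive == 0 and res.correct_dead == 0

    def test_malformed_patient_group_names_patient(self, temporal_vset):
        broken = temporal_vset.records.iloc[1:]
        vset = temporal_vset.__class__.__new__(temporal_vset.__class__)
        vset.records = broken
        vset.layout = "temporal"
        with pytest.raises(ConfigurationError, match=r"\d"):
            evaluate_temporal(ConstantModel("C"), vset)

    def test_static_temporal_consistency_for_constant_a(self, static_vset, temporal_vset):
        static_cls = group_labels(ConstantModel("A").predict(static_vset.records))[0]
        temporal_res = evaluate_temporal(ConstantModel("A"), temporal_vset, "neutral")
        assert static_cls == "CL1"
        assert temporal_res.correct_alive == temporal_res.n_alive


class TestCorrelation:
    def test_identical_vectors(self):
        rep = make_report({"a": 0.5, "b": 0.6, "c": 0.7})
        results = [result("a", 0.5, 1, 1), result("b", 0.6, 1, 1), result("c", 0.7, 1, 1)]
        assert internal_external_correlation(rep, results) == pytest.approx(1.0)

    def test_exact_reversal(self):
        rep = make_report({"a": 0.5, "b": 0.6, "c": 0.7})
        results = [result("a", 0.7, 1, 1), result("b", 0.6, 1, 1), result("c", 0.5, 1, 1)]
        assert internal_external_correlation(rep, results) == pytest.approx(-1.0)

    def test_hand_covariance_oracle(self):
        x = np.array([1, 2, 3, 5.0])
        y = np.array([1, 2, 3, 4.0])
        r_oracle = (
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        rep = make_report(dict(zip("abcd", x / 10)))
        results = [result(k, v / 10, 1, 1) for k, v in zip("abcd", y)]
        assert internal_external_correlation(rep, results) == pytest.approx(r_oracle, abs=1e-12)

    def test_mismatched_ids_rejected(self):
        rep = make_report({"a": 0.5, "b": 0.6, "c": 0.7})
        with pytest.raises(ValueError):
            internal_external_correlation(rep, [result("a", 0.5, 1, 1)])


class TestHourlyOutcomeModel:
    @staticmethod
    def _table(n, rng):
        return pd.DataFrame(
            rng.integers(1, 6, size=(n, 5)).astype(float),
            columns=["hour_5", "hour_4", "hour_3", "hour_2", "hour_1"],
        )

    def test_outcome_driven_by_final_hour_shows_in_odds_ratios(self):
        rng = np.random.default_rng(0)
        X = self._table(300, rng)
        y = np.where(X["hour_1"] >= 3, "died", "discharged_alive")
        out = hourly_outcome_model(X, y, backend="logistic_regression", seed=0)
        ors = out["odds_ratios"]
        assert np.abs(np.log(ors["hour_1"])) == np.abs(np.log(ors)).max()
        assert ors["hour_1"] > 1  # higher severity at hour 1 raises death odds

    def test_labels_independent_of_outcome_score_near_chance(self):
        rng = np.random.default_rng(1)
        X = self._table(500, rng)
        y = rng.choice(["died", "discharged_alive"], 500)
        out = hourly_outcome_model(X, y, backend="decision_tree", seed=1)
        assert 0.4 <= out["cv_f1_micro"] <= 0.6

    def test_separable_input_learned(self):
        rng = np.random.default_rng(2)
        X = self._table(200, rng)
        y = np.where(X[["hour_2", "hour_1"]].mean(axis=1) > 3, "died", "discharged_alive")
        out = hourly_outcome_model(X, y, backend="decision_tree", seed=2)
        assert out["cv_f1_micro"] >= 0.95

    def test_single_outcome_rejected(self):
        rng = np.random.default_rng(3)
        X = self._table(50, rng)
        with pytest.raises(ValueError):
            hourly_outcome_model(X, ["died"] * 50)

    def test_build_hourly_label_table_shape(self, temporal_vset):
        wide, outcomes = build_hourly_label_table(ConstantModel("B"), temporal_vset)
        assert wide.shape == (100, 5)
        np.testing.assert_allclose(wide, 2.0)
        assert set(outcomes) == {"discharged_alive", "died"}
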