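import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from icuconsensus import (
    agreement_summary,
    cohen_kappa,
    fleiss_kappa,
    interpret_cohen,
    interpret_fleiss,
    krippendorff_alpha,
)

# hand-worked two-rater example: p_o = 0.8, p_e = 0.33, kappa = 0.47/0.67
HAND_A = list("AAABBBCCCA")
HAND_B = list("AABBBCCCCA")
HAND_KAPPA = 0.47 / 0.67

# hand-worked 3 raters x 4 items: mean item agreement 2/3, chance 1/2, kappa 1/3
FLEISS_MATRIX = pd.DataFrame(
    [["A", "A", "A"], ["A", "A", "B"], ["B", "B", "B"], ["A", "B", "B"]]
)


def alpha_bruteforce(matrix, categories=None):
    """Independent oracle: alpha from direct within-item pair counting.

    D_o = sum over items of (disagreeing ordered pairs)/(m_u - 1), divided by
    the number of pairable values; D_e from drawing value pairs at random from
    the pooled coincidence margins.
    """
    arr = pd.DataFrame(matrix).to_numpy(dtype=object)
    values = []
    d_o_num = 0.0
    n_pairable = 0
    for row in arr:
        row = [v for v in row if v is not None and v == v]
        if len(row) < 2:
            continue
        values.extend(row)
        n_pairable += len(row)
        dis = sum(a != b for a, b in itertools.permutations(row, 2))
        d_o_num += dis / (len(row) - 1)
    d_o = d_o_num / n_pairable
    counts = pd.Series(values).value_counts()
    n = counts.sum()
    d_e = sum(
        counts[a] * counts[b] for a, b in itertools.permutations(counts.index, 2) if a != b
    ) / (n * (n - 1))
    return 1 - d_o / d_e


class TestCohenKappa:
    def test_identical_vectors_give_one(self):
        assert cohen_kappa(list("ABCAB"), list("ABCAB")) == pytest.approx(1.0)

    def test_perfect_symmetric_disagreement_gives_minus_one(self):
        assert cohen_kappa(list("AABB"), list("BBAA")) == pytest.approx(-1.0)

    def test_hand_worked_contingency_example(self):
        assert cohen_kappa(HAND_A, HAND_B) == pytest.approx(HAND_KAPPA, abs=1e-9)

    def test_constant_identical_raters_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="constant"):
            assert cohen_kappa(["A"] * 5, ["A"] * 5) == 1.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            cohen_kappa(["A"], ["A", "B"])
        with pytest.raises(ValueError):
            cohen_kappa([], [])


class TestFleissKappa:
    def test_unanimous_matrix_gives_one(self):
        m = pd.DataFrame([["B"] * 4] * 6)
        with pytest.warns(UserWarning):
            assert fleiss_kappa(m) == 1.0

    def test_hand_worked_three_rater_example(self):
        assert fleiss_kappa(FLEISS_MATRIX) == pytest.approx(1 / 3, abs=1e-9)

    def test_random_labels_centre_on_zero(self):
        vals = []
        for s in range(20):
            rng = np.random.default_rng(s)
            m = pd.DataFrame(rng.choice(list("ABCDE"), size=(500, 11)))
            vals.append(fleiss_kappa(m))
        assert abs(np.mean(vals)) < 0.05

    def test_incomplete_matrix_rejected(self):
        m = FLEISS_MATRIX.copy()
        m.iloc[0, 0] = None
        with pytest.raises(ValueError):
            fleiss_kappa(m)

    def test_declared_unused_categories_do_not_change_value(self):
        assert fleiss_kappa(FLEISS_MATRIX, categories=list("ABCDE")) == pytest.approx(
            fleiss_kappa(FLEISS_MATRIX, categories=["A", "B"]), abs=1e-12
        )


class TestKrippendorffAlpha:
    def test_unanimous_matrix_gives_one(self):
        with pytest.warns(UserWarning):
            assert krippendorff_alpha(pd.DataFrame([["C"] * 3] * 5)) == 1.0

    def test_matches_bruteforce_oracle_on_hand_example(self):
        assert krippendorff_alpha(FLEISS_MATRIX) == pytest.approx(
            alpha_bruteforce(FLEISS_MATRIX), abs=1e-9
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.choice(list("ABC"), size=(30, 5)))
        assert krippendorff_alpha(m) == pytest.approx(alpha_bruteforce(m), abs=1e-9)

    def test_fully_missing_rater_column_is_ignored(self):
        m = FLEISS_MATRIX.copy()
        m[3] = None
        assert krippendorff_alpha(m) == pytest.approx(
            krippendorff_alpha(FLEISS_MATRIX), abs=1e-12
        )

    def test_all_items_single_rating_rejected(self):
        m = pd.DataFrame({"r1": ["A", "B"], "r2": [None, None]})
        with pytest.raises(ValueError):
            krippendorff_alpha(m)


class TestInterpretationScales:
    @pytest.mark.parametrize(
        "kappa,expected",
        [(0.255, "Minimal"), (0.10, "None"), (0.48, "Weak"), (0.70, "Moderate"),
         (0.85, "Strong"), (0.95, "Almost Perfect")],
    )
    def test_cohen_scale(self, kappa, expected):
        assert interpret_cohen(kappa) == expected

    @pytest.mark.parametrize(
        "kappa,expected",
        [(0.383, "Fair"), (0.174, "Slight"), (0.267, "Fair"), (-0.1, "Poor"),
         (0.55, "Moderate"), (0.75, "Substantial")],
    )
    def test_fleiss_scale(self, kappa, expected):
        assert interpret_fleiss(kappa) == expected


class TestInvariants:
    def test_category_relabelling_leaves_nominal_statistics_unchanged(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.choice(list("ABCDE"), size=(40, 4)))
        swap = dict(zip("ABCDE", "EDCBA"))
        m2 = m.map(swap.get)
        assert fleiss_kappa(m) == pytest.approx(fleiss_kappa(m2), abs=1e-12)
        assert krippendorff_alpha(m) == pytest.approx(krippendorff_alpha(m2), abs=1e-12)
        assert cohen_kappa(m[0], m[1]) == pytest.approx(cohen_kappa(m2[0], m2[1]), abs=1e-12)

    def test_rater_order_invariance(self):
        rng = np.random.default_rng(8)
        m = pd.DataFrame(rng.choice(list("ABC"), size=(30, 5)))
        shuffled = m[[3, 1, 4, 0, 2]]
        shuffled.columns = range(5)
        assert fleiss_kappa(m) == pytest.approx(fleiss_kappa(shuffled), abs=1e-12)

    def test_statistics_bounded(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            m = pd.DataFrame(rng.choice(list("AB"), size=(20, 3)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                assert -1 <= fleiss_kappa(m) <= 1
                assert krippendorff_alpha(m) <= 1
                assert -1 <= cohen_kappa(m[0], m[1]) <= 1


class TestAgreementSummary:
    def test_pairwise_matrix_symmetric_unit_diagonal(self, default_panel):
        summary = agreement_summary(default_panel.labels)
        pw = summary.pairwise_kappa
        np.testing.assert_allclose(pw, pw.T)
        np.testing.assert_allclose(np.diag(pw), 1.0)

    def test_mean_excludes_diagonal(self):
        m = pd.DataFrame({"a": list("ABAB"), "b": list("ABAB"), "c": list("BABA")})
        s = agreement_summary(m)
        # pairs: (a,b)=1, (a,c)=-1, (b,c)=-1 -> mean -1/3
        assert s.mean_pairwise_kappa == pytest.approx(-1 / 3)

    def test_single_stratum_matches_overall(self, default_panel):
        strata = np.array(["all"] * default_panel.n_records)
        s = agreement_summary(default_panel.labels, strata=strata)
        sub = s.per_stratum["all"]
        assert sub.fleiss_kappa == pytest.approx(s.fleiss_kappa, abs=1e-12)
        assert sub.mean_pairwise_kappa == pytest.approx(s.mean_pairwise_kappa, abs=1e-12)

    def test_tiny_stratum_skipped_with_warning(self, default_panel):
        strata = np.array(["big"] * (default_panel.n_records - 1) + ["tiny"])
        with pytest.warns(UserWarning, match="tiny"):
            s = agreement_summary(default_panel.labels, strata=strata)
        assert "tiny" not in s.per_stratum and "big" in s.per_stratum

    def test_interpretations_present(self, default_panel):
        s = agreement_summary(default_panel.labels)
        assert s.interpretation["cohen"] in {
            "None", "Minimal", "Weak", "Moderate", "Strong", "Almost Perfect"
        }
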