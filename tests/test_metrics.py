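"""Unit and property tests for the core statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from templatest.exceptions import ComputationError, ValidationError
from templatest.metrics import (
    behavioural_relevance,
    brute_force_A,
    compute_templates,
    fano_factor,
    mann_whitney_u,
    pearson_correlation,
    row_correlations,
    specificity_index,
    vargha_delaney_A,
    yule_kendall,
)
from templatest.session import ConditionTemplate

from conftest import make_session

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)
# mixing in small integers makes exact ties common
tied_values = st.one_of(st.integers(min_value=-3, max_value=3).map(float), finite_floats)
samples = st.lists(tied_values, min_size=1, max_size=30)


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [-1, -2, -3], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
        ],
    )
    def test_values(self, x, y, expected):
        assert pearson_correlation(x, y) == pytest.approx(expected)

    def test_zero_variance_is_undefined_marker(self):
        assert math.isnan(pearson_correlation([1, 1, 1], [1, 2, 3]))

    @pytest.mark.parametrize("x, y", [([1], [2]), ([1, 2], [1, 2, 3])])
    def test_validation(self, x, y):
        with pytest.raises(ValidationError):
            pearson_correlation(x, y)

    def test_row_correlations_matches_scalar(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 6))
        v = rng.normal(size=6)
        expected = [pearson_correlation(row, v) for row in X]
        np.testing.assert_allclose(row_correlations(X, v), expected, atol=1e-12)


class TestTemplates:
    def test_means_and_counts(self):
        sess = make_session(
            [[0, 2], [2, 4], [10, 20]], ["A", "A", "B"]
        )
        tpl = compute_templates(sess)
        np.testing.assert_allclose(tpl["A"].mean_vector, [1, 3])
        np.testing.assert_allclose(tpl["B"].mean_vector, [10, 20])
        assert tpl["A"].n_trials == 2 and tpl["B"].n_trials == 1

    def test_missing_condition_named(self):
        sess = make_session([[0, 2]], ["A"])
        with pytest.raises(ValidationError, match="B"):
            compute_templates(sess, ["B"])


class TestSpecificity:
    def test_identical_templates_give_zero(self, two_condition_session):
        tpl = compute_templates(two_condition_session)
        same = {"A": tpl["A"], "B": tpl["A"]}
        res = specificity_index(
            two_condition_session, same,
            correct_of={"A": "A", "B": "A"}, wrong_of={"A": "B", "B": "B"},
        )
        np.testing.assert_allclose(res.rho, 0.0, atol=1e-12)

    def test_anticorrelated_templates_attain_bound(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        sess = make_session([v], ["A"])
        tpl = {
            "A": ConditionTemplate("A", v, 1),
            "B": ConditionTemplate("B", -v, 1),
        }
        res = specificity_index(sess, tpl, {"A": "A"}, {"A": "B"})
        assert res.rho[0] == pytest.approx(2.0)

    def test_hand_worked_toy(self):
        # cor([2,1,4,3], r) = 0.6 and cor([4,3,2,1], r) = -1 for r=[1,2,3,4]
        sess = make_session([[1, 2, 3, 4]], ["A"])
        tpl = {
            "A": ConditionTemplate("A", [2, 1, 4, 3], 1),
            "B": ConditionTemplate("B", [4, 3, 2, 1], 1),
        }
        res = specificity_index(sess, tpl, {"A": "A"}, {"A": "B"})
        assert res.rho[0] == pytest.approx(1.6)

    def test_zero_variance_trial_excluded_with_reason(self):
        sess = make_session([[1, 2, 3], [5, 5, 5]], ["A", "A"])
        tpl = {
            "A": ConditionTemplate("A", [1, 2, 3], 2),
            "B": ConditionTemplate("B", [3, 2, 1], 2),
        }
        res = specificity_index(sess, tpl, {"A": "A"}, {"A": "B"})
        assert res.trial_ids == ["t0"]
        assert res.excluded_trials[0][0] == "t1"
        assert "zero-variance" in res.excluded_trials[0][1]

    def test_all_excluded_raises(self):
        sess = make_session([[5, 5, 5]], ["A"])
        tpl = {
            "A": ConditionTemplate("A", [1, 2, 3], 1),
            "B": ConditionTemplate("B", [3, 2, 1], 1),
        }
        with pytest.raises(ComputationError):
            specificity_index(sess, tpl, {"A": "A"}, {"A": "B"})

    def test_leave_one_out_changes_small_sample_rho(self, two_condition_session):
        tpl = compute_templates(two_condition_session)
        correct = {"A": "A", "B": "B"}
        wrong = {"A": "B", "B": "A"}
        res_in = specificity_index(two_condition_session, tpl, correct, wrong)
        res_loo = specificity_index(
            two_condition_session, tpl, correct, wrong, leave_one_out=True
        )
        # self-inclusion inflates the correct-template correlation
        assert np.mean(res_in.rho) > np.mean(res_loo.rho)

    @given(
        r=st.lists(finite_floats, min_size=3, max_size=8),
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=-100, max_value=100),
    )
    @settings(max_examples=200, derandomize=True)
    def test_affine_invariance(self, r, a, b):
        """ρ is unchanged by positive affine transforms of the trial vector."""
        r = np.asarray(r)
        tpl_c = np.arange(len(r), dtype=float)
        tpl_w = tpl_c[::-1].copy()
        c1 = pearson_correlation(tpl_c, r)
        c2 = pearson_correlation(tpl_w, r)
        d1 = pearson_correlation(tpl_c, a * r + b)
        d2 = pearson_correlation(tpl_w, a * r + b)
        if math.isnan(c1) or math.isnan(c2):
            assert math.isnan(d1) or math.isnan(d2)
        else:
            assert (c1 - c2) == pytest.approx(d1 - d2, abs=1e-9)


class TestRankStatistics:
    @pytest.mark.parametrize(
        "x, y, u_x",
        [
            ([1, 2], [3, 4], 0.0),
            ([1, 2, 3], [1, 2, 3], 4.5),  # n^2/2 under exchange symmetry
            ([1, 2, 3], [2, 3, 4], 2.0),
        ],
    )
    def test_u_examples(self, x, y, u_x):
        mw = mann_whitney_u(x, y)
        assert mw.U_X == pytest.approx(u_x)
        assert mw.U == pytest.approx(min(mw.U_X, mw.U_Y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    @given(x=samples, y=samples)
    @settings(max_examples=300, derandomize=True)
    def test_u_identity_and_scipy_agreement(self, x, y):
        mw = mann_whitney_u(x, y)
        assert mw.U_X + mw.U_Y == pytest.approx(mw.n_X * mw.n_Y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert mw.U_X == pytest.approx(ref)

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([4, 5, 6], [1, 2, 3], 1.0),
            ([1, 2, 3], [1, 2, 3], 0.5),
            ([1, 2, 3], [2, 3, 4], 2 / 9),
            ([5], [1], 1.0),
            ([1], [1], 0.5),
        ],
    )
    def test_A_examples(self, x, y, expected):
        assert vargha_delaney_A(x, y) == pytest.approx(expected)
        assert brute_force_A(x, y) == pytest.approx(expected)

    @given(x=samples, y=samples)
    @settings(max_examples=500, derandomize=True)
    def test_rank_A_equals_oracle_and_complement(self, x, y):
        a = vargha_delaney_A(x, y)
        assert a == brute_force_A(x, y)
        assert a + vargha_delaney_A(y, x) == pytest.approx(1.0, abs=1e-12)


class TestRelevance:
    @pytest.mark.parametrize(
        "x, y, omega",
        [
            ([1, 2, 3], [10, 11, 12], 1.0),
            ([1, 2, 3], [1, 2, 3], 0.5),
            ([1, 2, 3], [2, 3, 4], 7 / 9),
        ],
    )
    def test_values(self, x, y, omega):
        res = behavioural_relevance(x, y)
        assert res.status == "ok"
        assert res.omega == pytest.approx(omega)

    def test_small_group_flagged_undefined(self):
        res = behavioural_relevance([1.0], [1, 2, 3])
        assert res.status == "undefined"
        assert res.omega is None
        assert res.group_sizes == (1, 3)

    @given(x=st.lists(tied_values, min_size=2, max_size=25),
           y=st.lists(tied_values, min_size=2, max_size=25))
    @settings(max_examples=300, derandomize=True)
    def test_symmetry_and_range(self, x, y):
        a = behavioural_relevance(x, y)
        b = behavioural_relevance(y, x)
        assert a.omega == b.omega
        assert 0.5 <= a.omega <= 1.0


class TestShapeStatistics:
    @pytest.mark.parametrize(
        "sample, expected",
        [
            ([1, 2, 3, 4, 5], 0.0),
            ([0, 0, 0, 1, 10], 1.0),
        ],
    )
    def test_yule_kendall_values(self, sample, expected):
        assert yule_kendall(sample) == pytest.approx(expected)

    @given(s=st.lists(finite_floats, min_size=3, max_size=30))
    @settings(max_examples=200, derandomize=True)
    def test_yule_kendall_bounded_and_mirror_symmetric(self, s):
        g = yule_kendall(s)
        if not math.isnan(g):
            assert -1.0 <= g <= 1.0
        mirrored = np.concatenate([np.asarray(s), -np.asarray(s)])
        gm = yule_kendall(mirrored)
        if not math.isnan(gm):
            assert gm == pytest.approx(0.0, abs=1e-9)

    def test_zero_iqr_flagged(self):
        assert math.isnan(yule_kendall([2, 2, 2, 2]))

    def test_fano_examples(self):
        sess = make_session(
            [[1, 2, 0], [3, 2, 0]], ["A", "A"], modality="counts"
        )
        ff = fano_factor(sess, "A")
        assert ff[0] == pytest.approx(1.0)  # var 2 / mean 2
        assert ff[1] == pytest.approx(0.0)  # constant counts
        assert math.isnan(ff[2])  # zero-mean neuron

    def test_fano_poisson_near_one(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(5.0, size=(10_000, 1))
        sess = make_session(counts, ["A"] * 10_000, modality="counts")
        ff = fano_factor(sess, "A")[0]
        # var/mean of Poisson(5): SE of the Fano estimate ~ sqrt(2/n)
        assert abs(ff - 1.0) < 3 * math.sqrt(2 / 10_000)

    def test_fano_needs_two_trials(self):
        sess = make_session([[1, 2]], ["A"], modality="counts")
        with pytest.raises(ValidationError):
            fano_factor(sess, "A")
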