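"""Jackknife, neuron selection, subsampling, clustering, grouped metrics."""

import numpy as np
import pytest

from templatest.exceptions import ComputationError, ValidationError
from templatest.metrics import compute_templates, specificity_index
from templatest.population import (
    JackknifeResult,
    cluster_trials,
    covariate_split,
    jackknife_contributions,
    metrics_by_group,
    select_extreme_neurons,
    subsample_metrics,
)
from templatest.session import two_condition_pairing
from templatest.simulate import make_count_fixture

from conftest import make_session


def _pairing_maps(session):
    pair = two_condition_pairing(session)
    return {c: c for c in session.conditions}, pair


class TestJackknife:
    def test_identity_holds_on_random_sessions(self):
        rng = np.random.default_rng(1)
        for rep in range(5):
            sess = make_session(
                rng.normal(size=(14, 8)) + 1.0,
                ["A" if i % 2 else "B" for i in range(14)],
            )
            correct, wrong = _pairing_maps(sess)
            jk = jackknife_contributions(sess, correct, wrong)
            n = sess.n_neurons
            # independent recomputation of the identity per cell
            base = specificity_index(sess, compute_templates(sess), correct, wrong)
            for j in range(n):
                sub = sess.subset_neurons([k for k in range(n) if k != j])
                res_j = specificity_index(
                    sub, compute_templates(sub), correct, wrong
                )
                rho_del = dict(zip(res_j.trial_ids, res_j.rho))
                for i, tid in enumerate(base.trial_ids):
                    expected = n * base.rho[i] - (n - 1) * rho_del[tid]
                    assert jk.contributions[i, j] == pytest.approx(
                        expected, abs=1e-10
                    )

    def test_hand_worked_three_neuron_toy(self):
        sess = make_session(
            [[1.0, 2.0, 4.0], [2.0, 1.0, 3.0]], ["A", "B"]
        )
        correct, wrong = _pairing_maps(sess)
        jk = jackknife_contributions(sess, correct, wrong)
        # with single-trial templates rho_i = 1 - cor(other, r_i); deleting a
        # neuron leaves 2-point vectors whose correlations are +-1 or 0
        base = specificity_index(sess, compute_templates(sess), correct, wrong)
        for i in range(2):
            for j in range(3):
                keep = [k for k in range(3) if k != j]
                sub = sess.subset_neurons(keep)
                rho_del = specificity_index(
                    sub, compute_templates(sub), correct, wrong
                ).rho[i]
                assert jk.contributions[i, j] == pytest.approx(
                    3 * base.rho[i] - 2 * rho_del, abs=1e-12
                )

    def test_gamma_zero_for_symmetric_contributions(self):
        # a mirrored contribution set has zero quartile skewness
        from templatest.metrics import yule_kendall

        sym = np.concatenate([np.array([0.1, 0.4, 0.9]), -np.array([0.1, 0.4, 0.9])])
        assert yule_kendall(sym) == pytest.approx(0.0, abs=1e-12)

    def test_needs_two_neurons(self):
        sess = make_session([[1.0], [2.0]], ["A", "B"])
        with pytest.raises(ValidationError):
            jackknife_contributions(sess, *_pairing_maps(sess))


class TestExtremeNeurons:
    def _jk(self, medians):
        n = len(medians)
        return JackknifeResult(
            trial_ids=["t0"],
            neuron_ids=[f"n{j}" for j in range(n)],
            contributions=np.tile(medians, (1, 1)),
            base_rho=np.array([0.0]),
            neuron_median=np.asarray(medians, dtype=float),
            gamma_per_neuron=np.full(n, np.nan),
            gamma_pooled=float("nan"),
        )

    def test_counts_use_ceiling(self):
        jk = self._jk(np.arange(10.0))
        assert len(select_extreme_neurons(jk, 0.10, "top")) == 1
        jk7 = self._jk(np.arange(7.0))
        assert len(select_extreme_neurons(jk7, 0.10, "top")) == 1

    def test_matches_sort_oracle_and_disjoint(self):
        rng = np.random.default_rng(4)
        med = rng.normal(size=20)
        jk = self._jk(med)
        top = select_extreme_neurons(jk, 0.2, "top")
        bottom = select_extreme_neurons(jk, 0.2, "bottom")
        order = np.argsort(-med, kind="stable")
        assert top == [f"n{j}" for j in order[:4]]
        assert set(top).isdisjoint(bottom)

    def test_fraction_validated(self):
        jk = self._jk(np.arange(5.0))
        with pytest.raises(ValidationError):
            select_extreme_neurons(jk, 0.6, "top")


class TestSubsample:
    def test_full_fraction_reproduces_whole_population(self, two_condition_session):
        correct, wrong = _pairing_maps(two_condition_session)
        res = subsample_metrics(
            two_condition_session, correct, wrong, fractions=(1.0,),
            n_repeats=5, seed=0,
        )
        spec = specificity_index(
            two_condition_session, compute_templates(two_condition_session),
            correct, wrong,
        )
        np.testing.assert_allclose(res.median_rho[1.0], spec.median_rho())

    def test_shape_contract(self, two_condition_session):
        correct, wrong = _pairing_maps(two_condition_session)
        res = subsample_metrics(
            two_condition_session, correct, wrong,
            fractions=(0.5, 1.0), n_repeats=7, seed=1,
        )
        assert set(res.median_rho) == {0.5, 1.0}
        assert all(v.shape == (7,) for v in res.median_rho.values())

    def test_uniform_selectivity_keeps_median_rho_flat(self):
        """When selectivity is spread evenly over neurons, median rho should
        not trend with population size (rank correlation test over seeds)."""
        from scipy.stats import spearmanr

        fracs = (0.2, 0.4, 0.6, 0.8, 1.0)
        rs = []
        for seed in range(8):
            sess = make_count_fixture(
                n_neurons=40, n_trials_per_condition=60, rate_effect=1.5,
                seed=seed,
            )
            correct, wrong = _pairing_maps(sess)
            res = subsample_metrics(
                sess, correct, wrong, fractions=fracs, n_repeats=6, seed=seed
            )
            med = [float(np.median(res.median_rho[f])) for f in fracs]
            rs.append(spearmanr(fracs, med).statistic)
        # no systematic positive trend across seeds
        assert np.mean(rs) < 0.95

    def test_two_neuron_floor(self, two_condition_session):
        correct, wrong = _pairing_maps(two_condition_session)
        with pytest.raises(ValidationError):
            subsample_metrics(
                two_condition_session, correct, wrong, fractions=(0.1,)
            )


class TestClustering:
    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(0, 0.3, size=(15, 6))
        blob2 = rng.normal(4, 0.3, size=(15, 6))
        sess = make_session(np.vstack([blob1, blob2]), ["A"] * 30)
        res = cluster_trials(sess, seed=0)
        assert res.chosen_k == 2
        labels = np.array([res.labels[t] for t in sess.trial_ids])
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_silhouette_matches_textbook_formula(self):
        from sklearn.metrics import silhouette_score

        # 4 points, 2 clusters: {0, 1} and {10, 11} on a line (2nd dim const)
        X = np.array([[0.0, 0], [1, 0], [10, 0], [11, 0]])
        labels = np.array([0, 0, 1, 1])
        # hand evaluation: a(i)=1, b(i)=mean(9,10)=9.5 or (10,11)=10.5 etc.
        s_vals = []
        for i in range(4):
            same = [j for j in range(4) if labels[j] == labels[i] and j != i]
            other = [j for j in range(4) if labels[j] != labels[i]]
            a = np.mean([abs(X[i, 0] - X[j, 0]) for j in same])
            b = np.mean([abs(X[i, 0] - X[j, 0]) for j in other])
            s_vals.append((b - a) / max(a, b))
        assert silhouette_score(X, labels) == pytest.approx(np.mean(s_vals))

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(2)
        sess = make_session(rng.normal(size=(20, 5)), ["A"] * 20)
        r1 = cluster_trials(sess, seed=5)
        r2 = cluster_trials(sess, seed=5)
        assert r1.labels == r2.labels and r1.chosen_k == r2.chosen_k

    def test_degenerate_identical_trials_rejected(self):
        sess = make_session(np.ones((10, 4)), ["A"] * 10)
        with pytest.raises(ComputationError):
            cluster_trials(sess)


class TestGroupedMetrics:
    def test_identity_grouping_equals_ungrouped(self, two_condition_session):
        correct, wrong = _pairing_maps(two_condition_session)
        gm = metrics_by_group(
            two_condition_session, lambda r: "all", correct, wrong,
            min_group_size=2,
        )
        assert len(gm.groups) == 1
        assert gm.groups[0].median_rho == pytest.approx(gm.pooled.median_rho)
        assert gm.groups[0].relevance.omega == gm.pooled.relevance.omega

    def test_small_groups_skipped_with_reason(self, two_condition_session):
        correct, wrong = _pairing_maps(two_condition_session)
        grouping = {t: t for t in two_condition_session.trial_ids}  # singletons
        with pytest.raises(ComputationError):
            metrics_by_group(
                two_condition_session, grouping, correct, wrong, min_group_size=4
            )
        # mixed: one big group, one singleton
        ids = two_condition_session.trial_ids
        grouping = {t: ("big" if t != ids[-1] else "lone") for t in ids}
        gm = metrics_by_group(
            two_condition_session, grouping, correct, wrong, min_group_size=4
        )
        assert [g.label for g in gm.groups] == ["big"]
        assert gm.skipped and "insufficient trials" in gm.skipped[0][1]

    def test_covariate_split_median(self):
        rng = np.random.default_rng(0)
        covs = [{"pupil": float(v)} for v in np.arange(10)]
        sess = make_session(
            rng.normal(size=(10, 3)), ["A"] * 10, covariates=covs
        )
        split = covariate_split(sess, "pupil", n_bins=2)
        labels = [split[t] for t in sess.trial_ids]
        assert labels[:5] == ["pupil_q1"] * 5
        assert labels[5:] == ["pupil_q2"] * 5

    def test_latent_modes_raise_within_group_specificity(self):
        """Sessions with two hidden response modes per condition should show
        higher median rho within modes than pooled (sign test over seeds)."""
        from scipy.stats import binomtest

        n_seeds = 20
        wins = 0
        for seed in range(n_seeds):
            sess = make_count_fixture(
                n_neurons=40, n_trials_per_condition=80, rate_effect=2.0,
                latent_modes=True, mode_effect=1.0, mode_mix=1.0, seed=seed,
            )
            correct, wrong = _pairing_maps(sess)
            grouping = {
                r.trial_id: f"m{int(r.covariates['mode'])}"
                for r in sess.trial_records
            }
            gm = metrics_by_group(sess, grouping, correct, wrong, min_group_size=4)
            within = np.median([g.median_rho for g in gm.groups])
            if within > gm.pooled.median_rho:
                wins += 1
        assert binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.05
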