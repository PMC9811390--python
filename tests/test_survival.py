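"""Splitting, LASSO-Cox, RRS, cutpoint, log-rank, Cox and agreement tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mbdeform import survival as sv
from mbdeform import synthetic as syn


def make_clinical(n=100, strata=4, seed=0):
    rng = np.random.default_rng(seed)
    groups = np.repeat(["WNT", "SHH", "G3", "G4"][:strata], n // strata)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(len(groups))],
            "subgroup": groups,
            "os_days": rng.exponential(1000, len(groups)),
            "event": rng.integers(0, 2, len(groups)),
        }
    )


class TestSplitCohort:
    def test_70_30_split_preserves_strata(self):
        clin = make_clinical(100)
        train, test = sv.split_cohort(clin, 0.7, seed=1)
        assert len(train) == 72 or len(train) == 70  # 25 per stratum -> 17-18 train
        assert len(train) + len(test) == 100
        per = clin.set_index("subject_id").loc[train, "subgroup"].value_counts()
        assert all(17 <= c <= 18 for c in per)

    def test_fixed_seed_is_deterministic(self):
        clin = make_clinical(60)
        assert sv.split_cohort(clin, 0.7, seed=5) == sv.split_cohort(clin, 0.7, seed=5)

    def test_full_fraction_warns_of_empty_test_set(self):
        clin = make_clinical(40)
        with pytest.warns(UserWarning, match="empty test set"):
            train, test = sv.split_cohort(clin, 1.0, seed=0)
        assert not test and len(train) == 40

    def test_singleton_stratum_goes_to_training(self):
        clin = make_clinical(40)
        clin.loc[0, "subgroup"] = "G3/G4"
        with pytest.warns(UserWarning, match="single subject"):
            train, _ = sv.split_cohort(clin, 0.7, seed=0)
        assert clin.loc[0, "subject_id"] in train


def brute_force_partial_loglik(lp, time, event):
    """O(n^2) Breslow partial log-likelihood."""
    total = 0.0
    for i in range(len(lp)):
        if event[i]:
            risk = np.exp(lp[time >= time[i]]).sum()
            total += lp[i] - np.log(risk)
    return total


class TestCoxPartialLoglik:
    def test_matches_quadratic_brute_force(self, rng):
        for _ in range(5):
            n = 30
            lp = rng.standard_normal(n)
            t = rng.exponential(100, n)
            e = rng.integers(0, 2, n)
            e[0] = 1
            assert sv.cox_partial_loglik(lp, t, e) == pytest.approx(
                brute_force_partial_loglik(lp, t, e), rel=1e-10
            )

    def test_handles_ties_breslow(self):
        lp = np.array([0.5, -0.2, 0.1, 0.0])
        t = np.array([5.0, 5.0, 8.0, 9.0])
        e = np.array([1, 1, 1, 0])
        assert sv.cox_partial_loglik(lp, t, e) == pytest.approx(
            brute_force_partial_loglik(lp, t, e), rel=1e-10
        )


class TestFitLassoCox:
    def _sim(self, seed, beta, n=200, p=20):
        rng = np.random.default_rng(seed)
        names = [f"F_{i}" for i in range(p)]
        names[3] = "K_10"
        X = pd.DataFrame(rng.standard_normal((n, p)), columns=names)
        t, e = syn.simulate_survival(beta * X["K_10"].to_numpy(), 1 / 1500, 3000.0, rng)
        return X, t, e

    def test_infinite_penalty_gives_empty_model(self):
        X, t, e = self._sim(0, 1.0)
        m = sv.fit_lasso_cox(X, t, e, alpha=np.inf)
        assert m.selected_features == [] and m.coefficients == {}

    def test_true_feature_recovered_across_seeds(self):
        hits = 0
        for s in range(10):
            X, t, e = self._sim(100 + s, beta=1.0)
            m = sv.fit_lasso_cox(X, t, e, seed=s)
            hits += "K_10" in m.selected_features
        assert hits >= 8

    def test_pure_noise_selects_little(self):
        import warnings

        emptyish = 0
        k10 = 0
        for s in range(10):
            X, t, e = self._sim(200 + s, beta=0.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = sv.fit_lasso_cox(X, t, e, seed=s)
            emptyish += len(m.selected_features) <= 2
            k10 += "K_10" in m.selected_features
        assert emptyish >= 8
        assert k10 <= 2

    def test_no_events_raises(self):
        X, t, e = self._sim(0, 1.0, n=50)
        with pytest.raises(ValueError, match="no events"):
            sv.fit_lasso_cox(X, t, np.zeros_like(e))

    def test_one_se_rule_selects_no_more_than_min(self):
        X, t, e = self._sim(7, 1.0)
        m_min = sv.fit_lasso_cox(X, t, e, seed=7, rule="min")
        m_1se = sv.fit_lasso_cox(X, t, e, seed=7, rule="1se")
        assert len(m_1se.selected_features) <= len(m_min.selected_features)
        assert m_1se.alpha >= m_min.alpha


class TestComputeRRS:
    def test_weighted_sum(self):
        X = pd.DataFrame({"K_10": [2.0], "MD_25": [1.0], "junk": [99.0]})
        m = sv.RiskModel(["K_10", "MD_25"], {"K_10": 0.5, "MD_25": -0.2})
        assert sv.compute_rrs(X, m).iloc[0] == pytest.approx(0.8)

    def test_empty_model_scores_zero_and_ignores_unselected(self, rng):
        X = pd.DataFrame(rng.standard_normal((5, 3)), columns=["a", "b", "c"])
        m = sv.RiskModel([], {})
        assert (sv.compute_rrs(X, m) == 0).all()
        m2 = sv.RiskModel(["a"], {"a": 1.0})
        X2 = X.copy()
        X2["b"] = 1e9
        assert sv.compute_rrs(X, m2).equals(sv.compute_rrs(X2, m2))

    def test_missing_column_raises(self):
        m = sv.RiskModel(["K_10"], {"K_10": 1.0})
        with pytest.raises(ValueError, match="missing"):
            sv.compute_rrs(pd.DataFrame({"a": [1.0]}), m)


class TestLogrank:
    def test_hand_computed_four_subject_example(self):
        """A dies at t=1,2; B dies at t=3,4: O_A=2, E_A=1/2+1/3, V=17/36."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, int)
        g = np.array([True, True, False, False])
        o_a, e_a = 2.0, 0.5 + 1.0 / 3.0
        v = 1 * 0.5 * 0.5 + 1 * (1 / 3) * (2 / 3)  # hypergeometric variance terms
        expected = (o_a - e_a) ** 2 / v  # = 2.88235...
        chi2, p = sv.logrank_chi2(g, t, e)
        assert chi2 == pytest.approx(expected, rel=1e-12)
        assert p == pytest.approx(sps.chi2.sf(expected, 1), rel=1e-12)

    def test_agrees_with_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test

        for _ in range(5):
            n = 60
            t = rng.exponential(100, n)
            e = rng.integers(0, 2, n)
            g = rng.random(n) < 0.5
            if e[g].sum() == 0 or e[~g].sum() == 0:
                continue
            chi2, p = sv.logrank_chi2(g, t, e)
            ref = logrank_test(t[g], t[~g], e[g], e[~g])
            assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2, 3, 1, 2, 3])
        e = np.ones(6, int)
        g = np.array([True] * 3 + [False] * 3)
        chi2, p = sv.logrank_chi2(g, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_km_without_censoring_is_empirical_survival(self, rng):
        t = rng.exponential(50, 40).round(1)
        e = np.ones(40, int)
        labels = np.array(["lo"] * 20 + ["hi"] * 20)
        res = sv.km_logrank(labels, t, e)
        times, surv = res.curves["lo"]
        tl = t[:20]
        for tt, ss in zip(times, surv):
            assert ss == pytest.approx((tl > tt).mean(), abs=1e-12)


class TestFindCutpoint:
    def test_separable_construction_cuts_between_clusters(self, rng):
        # low-score cluster dies late, high-score cluster dies early: the
        # log-rank-maximizing threshold must fall in the score gap
        scores = np.concatenate([rng.uniform(0, 1, 20), rng.uniform(5, 6, 20)])
        t = np.concatenate([rng.uniform(2000, 3000, 20), rng.uniform(50, 300, 20)])
        e = np.ones(40, int)
        cut = sv.find_cutpoint(scores, t, e)
        assert 1.0 < cut < 5.0

    def test_identical_outcomes_return_lowest_admissible_cut(self):
        scores = np.arange(10.0)
        t = np.full(10, 100.0)
        e = np.ones(10, int)
        cut = sv.find_cutpoint(scores, t, e, min_group_frac=0.2)
        assert cut == pytest.approx(1.5)  # first midpoint leaving >= 2 on each side

    def test_min_group_guard_can_make_all_cuts_inadmissible(self):
        scores = np.arange(5.0)
        t = np.arange(1.0, 6.0)
        e = np.ones(5, int)
        with pytest.raises(ValueError, match="admissible"):
            sv.find_cutpoint(scores, t, e, min_group_frac=0.5)

    def test_invariant_to_monotone_transform_of_scores(self, rng):
        scores = rng.standard_normal(60)
        t = rng.exponential(500, 60)
        e = rng.integers(0, 2, 60)
        e[:10] = 1
        cut1 = sv.find_cutpoint(scores, t, e)
        cut2 = sv.find_cutpoint(np.exp(scores), t, e)
        assert np.array_equal(scores > cut1, np.exp(scores) > cut2)


class TestCoxFit:
    def test_null_covariate_has_c_index_near_half(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "os_days": rng.exponential(1000, n),
                "event": rng.integers(0, 2, n),
                "x": rng.standard_normal(n),
            }
        )
        df.loc[:20, "event"] = 1
        fit = sv.cox_fit(df, continuous=("x",))
        assert abs(fit.c_index - 0.5) < 0.05
        assert abs(np.log(fit.hr_per_stratum["x"])) < 0.2

    def test_perfect_predictor_has_c_index_one(self):
        t = np.linspace(10, 1000, 50)
        df = pd.DataFrame({"os_days": t, "event": np.ones(50, int), "x": -t})
        c, se = sv.concordance(df["os_days"], df["event"], df["x"])
        assert c == pytest.approx(1.0)

    def test_binary_covariate_hr_recovery(self):
        inside = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(3000 + s)
            n = 400
            g = rng.random(n) < 0.5
            t, e = syn.simulate_survival(np.log(2.0) * g, 1 / 1500, 3000.0, rng)
            df = pd.DataFrame({"os_days": t, "event": e, "g": g.astype(float)})
            fit = sv.cox_fit(df, continuous=("g",))
            inside += 1.6 <= fit.hr_per_stratum["g"] <= 2.5
        assert inside / reps >= 0.90

    def test_categorical_strata_report_baseline_as_one(self, rng):
        n = 120
        df = pd.DataFrame(
            {
                "os_days": rng.exponential(800, n),
                "event": np.ones(n, int),
                "subgroup": rng.choice(["WNT", "SHH", "G3", "G4"], n),
            }
        )
        fit = sv.cox_fit(df, categorical={"subgroup": "G3"})
        assert fit.hr_per_stratum["subgroup=G3"] == 1.0
        assert {"subgroup=WNT", "subgroup=SHH", "subgroup=G4"} <= set(fit.hr_per_stratum)

    def test_missing_subgroup_rows_are_dropped(self, rng):
        n = 60
        df = pd.DataFrame(
            {
                "os_days": rng.exponential(800, n),
                "event": np.ones(n, int),
                "subgroup": rng.choice(["WNT", "SHH", "G3", "G4"], n).astype(object),
            }
        )
        df.loc[:9, "subgroup"] = np.nan
        with pytest.warns(UserWarning, match="dropped 10"):
            fit = sv.cox_fit(df, categorical={"subgroup": "G3"})
        assert fit.n == 50


class TestAgreementTests:
    def test_mcnemar_symmetric_discordance_is_null(self):
        assert sv.mcnemar_test(np.array([[3, 5], [5, 2]])) == (0.0, 1.0)

    def test_mcnemar_hand_example(self):
        chi2, p = sv.mcnemar_test(np.array([[5, 10], [0, 5]]))
        assert chi2 == pytest.approx(10.0)
        assert p == pytest.approx(sps.chi2.sf(10.0, 1), rel=1e-9)
        assert p == pytest.approx(0.00157, abs=5e-5)

    def test_mcnemar_no_discordance_convention(self):
        assert sv.mcnemar_test(np.array([[7, 0], [0, 3]])) == (0.0, 1.0)

    def test_mcnemar_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            sv.mcnemar_test(np.array([[1, -2], [0, 1]]))

    def test_chi2_hand_example_4x2(self):
        chi2, p = sv.chi2_independence(np.array([[10, 0], [0, 10], [10, 0], [0, 10]]))
        assert chi2 == pytest.approx(40.0)
        assert p == pytest.approx(sps.chi2.sf(40.0, 3), rel=1e-9)

    def test_chi2_proportional_rows_are_independent(self):
        chi2, p = sv.chi2_independence(np.array([[10, 20], [5, 10], [1, 2]]))
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_chi2_scales_linearly_with_counts(self, rng):
        tab = rng.integers(1, 30, (4, 2))
        c1, _ = sv.chi2_independence(tab)
        c2, _ = sv.chi2_independence(2 * tab)
        assert c2 == pytest.approx(2 * c1, rel=1e-9)


class TestEndToEndChain:
    def test_true_predictor_beats_permuted_predictor_in_concordance(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            n = 150
            x = rng.standard_normal(n)
            t, e = syn.simulate_survival(x, 1 / 1500, 3000.0, rng)
            c_true, _ = sv.concordance(t, e, x)
            c_perm, _ = sv.concordance(t, e, rng.permutation(x))
            assert c_true > c_perm

    def test_rrs_experiment_stratifies_synthetic_cohort(self):
        ccfg = syn.CohortSimConfig(n_subjects=210, seed=424)
        cohort = syn.generate_cohort(ccfg)
        ex = sv.rrs_stratification_experiment(
            cohort.features, cohort.clinical, train_fraction=150 / 210, seed=424
        )
        assert ex.model.selected_features
        assert ex.train_km.p < 0.01
        assert ex.test_km is not None and ex.test_km.p < 0.05
        assert set(ex.risk_group.unique()) <= {"low", "high"}
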