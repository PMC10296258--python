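"""Kaplan-Meier, log-rank, Cox, PH check, logistic/ROC, stratification."""

import numpy as np
import pandas as pd
import pytest

from metabotype import (
    cox_fit, km_curve, logistic_fit, logrank_test, ph_test, roc_auc,
    stratified_analysis, survival_at, three_year_status,
)


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        curve = km_curve([1, 2, 3, 4], [1, 1, 1, 1])
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert survival_at(curve, t) == pytest.approx(s)

    def test_hand_product_limit_with_censoring(self):
        times = [1, 2, 3, 4, 5]
        events = [1, 0, 1, 0, 1]
        curve = km_curve(times, events)
        assert survival_at(curve, 1) == pytest.approx(4 / 5)
        assert survival_at(curve, 3) == pytest.approx(4 / 5 * 2 / 3)
        assert survival_at(curve, 5) == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        curve = km_curve([1, 2, 3], [0, 0, 0])
        assert survival_at(curve, 3) == pytest.approx(1.0)

    def test_invariants(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(2, 50)
        e = rng.integers(0, 2, 50)
        e[0] = 1
        curve = km_curve(t, e)
        assert survival_at(curve, 0) == pytest.approx(1.0)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all((curve.survival >= 0) & (curve.survival <= 1))

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])
        with pytest.raises(ValueError):
            km_curve([0.0, 1.0], [1, 1])


def hand_logrank_two_group(times, events, groups):
    """From-definition O-E / V log-rank for two groups."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_duplicated_group_is_null(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 1])
        chi2, df, p = logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 1, 1, 0, 1]
        groups = [0, 1, 0, 1, 0, 1]
        t = np.array(times, float)
        e = np.array(events)
        g = np.array(groups)
        chi2, _, _ = logrank_test([
            (t[g == 0], e[g == 0]), (t[g == 1], e[g == 1])])
        assert chi2 == pytest.approx(hand_logrank_two_group(times, events,
                                                            groups),
                                     abs=1e-10)

    def test_three_identical_groups(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 1])
        chi2, df, p = logrank_test([(t, e)] * 3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([(np.array([1.0]), np.array([1])),
                          (np.array([]), np.array([]))])


def grid_search_cox_beta(x, times, events):
    """Brute-force maximizer of the (no-ties) Cox partial likelihood."""
    order = np.argsort(times)
    x, times, events = x[order], times[order], events[order]
    betas = np.arange(-5, 5, 1e-3)
    best, best_ll = None, -np.inf
    for b in betas:
        ll = 0.0
        for i in range(len(x)):
            if events[i]:
                risk = x[i:]  # all with time >= t_i
                ll += b * x[i] - np.log(np.exp(b * risk).sum())
        if ll > best_ll:
            best, best_ll = b, ll
    return best


class TestCox:
    def test_matches_grid_search_oracle(self):
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        times = np.array([1.3, 2.1, 3.7, 4.2, 5.9, 6.4])
        events = np.array([1, 1, 1, 1, 1, 0])
        res = cox_fit(pd.DataFrame({"x": x}), times, events)
        ref = grid_search_cox_beta(x, times, events)
        assert res.summary.loc["x", "coef"] == pytest.approx(ref, abs=2e-3)
        assert res.hazard_ratio("x") == pytest.approx(
            np.exp(res.summary.loc["x", "coef"]))

    def test_constant_covariate_named(self):
        df = pd.DataFrame({"flat": np.ones(6), "x": np.arange(6.0)})
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, np.arange(1.0, 7.0), np.ones(6, int))

    def test_collinear_covariates_rejected(self):
        x = np.arange(6.0)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1})
        with pytest.raises(ValueError, match="collinear"):
            cox_fit(df, np.arange(1.0, 7.0), np.ones(6, int))

    def test_missing_rows_dropped_and_counted(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df.loc[:4, "x"] = np.nan
        t = rng.exponential(1, 30) + 0.01
        res = cox_fit(df, t, np.ones(30, int))
        assert res.n == 25
        assert res.n_dropped_missing == 5

    def test_matches_logrank_score_scale(self):
        """Single binary covariate: the Cox model and the log-rank test
        agree on presence/absence of a group difference."""
        rng = np.random.default_rng(5)
        x = np.r_[np.zeros(25), np.ones(25)]
        t = rng.exponential(1.0, 50) / np.exp(1.2 * x)
        e = np.ones(50, int)
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        chi2, _, p_lr = logrank_test([(t[x == 0], e[x == 0]),
                                      (t[x == 1], e[x == 1])])
        assert (res.summary.loc["x", "p"] < 0.05) == (p_lr < 0.05)


class TestPHTest:
    def test_crossing_hazards_detected(self):
        # group 1 dies early then plateaus; group 0 steady -> strong
        # time-varying effect
        rng = np.random.default_rng(2)
        n = 120
        z = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        t0 = rng.weibull(2.2, n // 2)  # increasing hazard
        t1 = rng.weibull(0.5, n // 2)  # sharply decreasing hazard
        t = np.r_[t0, t1] + 1e-3
        p = ph_test(t, np.ones(n, int), z)
        assert p < 0.05

    def test_proportional_hazards_not_rejected_typically(self):
        rng = np.random.default_rng(3)
        rejections = 0
        for _ in range(20):
            z = rng.integers(0, 2, 60).astype(float)
            t = rng.exponential(1.0, 60) / np.exp(0.7 * z)
            rejections += ph_test(t, np.ones(60, int), z) < 0.05
        assert rejections <= 4

    def test_transform_validated(self):
        with pytest.raises(ValueError):
            ph_test([1.0, 2.0], [1, 1], [0.0, 1.0], transform="sqrt")


class TestThreeYearStatus:
    def test_classification_rules(self):
        status = three_year_status([2.5, 4.0, 2.0], [1, 0, 0])
        assert status[0] == 1.0    # event before horizon -> dead
        assert status[1] == 0.0    # followed past horizon -> alive
        assert np.isnan(status[2])  # censored early -> excluded
        assert status.attrs["n_excluded"] == 1

    def test_event_after_horizon_counts_alive(self):
        status = three_year_status([4.5], [1])
        assert status[0] == 0.0


class TestLogistic:
    def test_two_by_two_closed_form(self):
        # exposed: 10 dead / 10 alive; unexposed: 5 dead / 20 alive
        x = np.r_[np.ones(20), np.zeros(25)]
        y = np.r_[np.ones(10), np.zeros(10), np.ones(5), np.zeros(20)]
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.params["x"] == pytest.approx(np.log(4.0), abs=1e-6)

    def test_independent_outcome_flat_slope(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = np.r_[np.ones(10), np.zeros(10), np.ones(10), np.zeros(10)]
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-6)

    def test_intercept_only_logit_of_mean(self):
        y = np.r_[np.ones(3), np.zeros(7)]
        fit = logistic_fit(pd.DataFrame(index=range(10)), y)
        assert fit.params["const"] == pytest.approx(np.log(0.3 / 0.7),
                                                    abs=1e-6)

    def test_perfect_separation_flagged_and_capped(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.copy()
        fit = logistic_fit(pd.DataFrame({"x": x}), y)
        assert fit.separated
        assert np.abs(fit.params.to_numpy()).max() <= 20.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(pd.DataFrame({"x": [0.0, 1.0]}), [1, 1])


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == pytest.approx(1.0)

    def test_pair_enumeration_example(self):
        res = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)  # 3 concordant of 4 pairs

    def test_ties_give_half(self):
        res = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = roc_auc(scores, y).auc
        b = roc_auc(np.exp(3 * scores) + 7, y).auc
        assert a == pytest.approx(b)

    def test_pair_enumeration_oracle_random(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        pos, neg = scores[y == 1], scores[y == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert roc_auc(scores, y).auc == pytest.approx(
            conc / (len(pos) * len(neg)))


def synthetic_clinical(seed=0, n=240, hr_smoker=3.0):
    from metabotype import SimulationConfig, generate_clinical, \
        generate_survival

    cfg = SimulationConfig(seed=seed, n_patients=n,
                           hr_subtypeA_smoker=hr_smoker)
    clin = generate_survival(generate_clinical(cfg), cfg)
    clin["subtype"] = clin["true_subtype"]
    return clin.set_index("id")


class TestStratified:
    def test_duplicated_stratum_identical(self):
        clin = synthetic_clinical(seed=1)
        rep = stratified_analysis(clin, strata=("ever_smokers",
                                                "ever_smokers"))
        # dict keys collapse; run twice explicitly instead
        a = stratified_analysis(clin, strata=("ever_smokers",))
        b = stratified_analysis(clin, strata=("ever_smokers",))
        assert a["ever_smokers"]["os"]["logrank"] == \
            b["ever_smokers"]["os"]["logrank"]
        assert rep["ever_smokers"]["n"] == a["ever_smokers"]["n"]

    def test_nested_roc_dominance_on_training_fit(self):
        clin = synthetic_clinical(seed=2)
        rep = stratified_analysis(clin)
        roc = rep["ever_smokers"]["three_year_roc"]
        assert roc["hpv_plus_subtype"]["auc"] >= roc["hpv_only"]["auc"] - 1e-9

    def test_subtype_effect_concentrated_in_smokers(self):
        clin = synthetic_clinical(seed=3)
        rep = stratified_analysis(clin)
        ever = rep["ever_smokers"]["os"]["cox"]["unadjusted"]
        never = rep["never_smokers"]["os"]["cox"]["unadjusted"]
        assert ever["hr"] > 1.3
        lo, hi = never["ci"]
        assert lo <= 1.0 <= hi

    def test_unfollowed_subjects_excluded(self):
        clin = synthetic_clinical(seed=4)
        rep = stratified_analysis(clin)
        assert rep["n_total"] == int(clin["followed"].sum())
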