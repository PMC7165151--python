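"""Survival-suite tests: KM by hand, log-rank/score identity, Cox recovery."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from codsig import (ConvergenceError, SimulationConfig, ValidationError,
                    backward_select, cox_fit, cox_score_test,
                    interaction_analysis, km_estimate, logrank_test,
                    simulate_survival)


def two_arm(seed, n=150, beta=0.7, censor=0.3, ties=False):
    """Small survival dataset with one binary covariate."""
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=n).astype(float)
    t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
    c = rng.exponential(1.0 / (0.05 * censor / (1 - censor))) if censor else \
        np.full(n, np.inf)
    times = np.minimum(t, c)
    events = t <= c
    if ties:
        times = np.ceil(times)  # month-resolution grid forces tied deaths
    return pd.DataFrame({"x": x}), times, events


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = km_estimate([3.0, 5.0, 8.0], [False, False, False])
        assert curve.times.size == 0
        assert curve.survival_at(100.0) == 1.0

    def test_three_events_product_limit_by_hand(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_single_subject_step(self):
        curve = km_estimate([5.0], [True])
        assert curve.survival_at(4.999) == 1.0
        assert curve.survival_at(5.0) == 0.0

    def test_all_event_data_equals_empirical_survival(self, rng):
        times = rng.exponential(10.0, size=200)
        curve = km_estimate(times, np.ones(200, bool))
        for t in np.quantile(times, [0.1, 0.5, 0.9]):
            assert curve.survival_at(t) == pytest.approx(np.mean(times > t))

    def test_matches_lifelines_with_censoring(self, rng):
        times = np.ceil(rng.exponential(10.0, size=100))
        events = rng.random(100) < 0.7
        curve = km_estimate(times, events)
        ref = KaplanMeierFitter().fit(times, events)
        for t in curve.times:
            assert curve.survival_at(t) == pytest.approx(
                float(ref.survival_function_at_times(t).iloc[0]), abs=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([-1.0], [True])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        events = [True] * 6
        res = logrank_test(times, events, [0, 0, 0, 1, 1, 1])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_one_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1.0, 2.0], [True, True], [0, 0])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines(self, seed):
        X, times, events = two_arm(seed, ties=True)
        ours = logrank_test(times, events, X["x"].astype(int))
        g = X["x"] == 1
        ref = ll_logrank(times[~g], times[g], events[~g], events[g])
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_cox_breslow_score_test(self, seed):
        # untied continuous times: score test at beta=0 is the log-rank chi2
        X, times, events = two_arm(seed, n=60, ties=False)
        lr = logrank_test(times, events, X["x"].astype(int))
        score = cox_score_test(X, times, events, ties="breslow")
        assert abs(lr.statistic - score.statistic) < 1e-10

    def test_detects_strong_hazard_difference(self):
        X, times, events = two_arm(0, n=600, beta=np.log(2.0), censor=0.0)
        assert logrank_test(times, events, X["x"].astype(int)).p_value < 1e-4


class TestCoxFit:
    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"noise": rng.normal(size=3000)})
        times = rng.exponential(20.0, size=3000)
        fit = cox_fit(X, times, np.ones(3000, bool))
        term = fit["noise"]
        assert abs(term.coef) < 3 * term.se
        assert term.ci_low < 1.0 < term.ci_high

    def test_two_group_exponential_matches_rate_ratio(self):
        cfg = SimulationConfig(seed=2, chemo_assign_prob=0.0, censor_rate=0.0,
                               true_hr_cod=2.0)
        labels = ["INT"] * 1000 + ["COD"] * 1000
        times, events, _ = simulate_survival(labels, cfg,
                                             rng=np.random.default_rng(2))
        is_cod = np.array([lab == "COD" for lab in labels], float)
        rate_ratio = ((events[is_cod == 1].sum() / times[is_cod == 1].sum())
                      / (events[is_cod == 0].sum() / times[is_cod == 0].sum()))
        fit = cox_fit(pd.DataFrame({"cod": is_cod}), times, events)
        assert fit["cod"].hr == pytest.approx(rate_ratio, rel=0.05)

    # Reference values computed with R survival::coxph (eps 1e-12) on the
    # dataset frozen by two_arm(3, n=200, ties=True) + rng(4) normals.
    _R_REFERENCE = {
        "efron": {"x": 0.9914492, "z": -0.3694355, "loglik": -330.8790},
        "breslow": {"x": 0.9690307, "z": -0.3583175, "loglik": -333.1626},
    }

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_r_coxph_with_tied_data(self, ties):
        X, times, events = two_arm(3, n=200, ties=True)
        X["z"] = np.random.default_rng(4).normal(size=200)
        fit = cox_fit(X, times, events, ties=ties)
        ref = self._R_REFERENCE[ties]
        assert fit["x"].coef == pytest.approx(ref["x"], abs=1e-6)
        assert fit["z"].coef == pytest.approx(ref["z"], abs=1e-6)
        assert fit.loglik == pytest.approx(ref["loglik"], abs=1e-3)

    def test_matches_lifelines_with_tied_data(self):
        # lifelines stops earlier than our 1e-9 coefficient tolerance, so the
        # agreement bound is its convergence precision, not ours
        X, times, events = two_arm(3, n=200, ties=True)
        X["z"] = np.random.default_rng(4).normal(size=200)
        fit = cox_fit(X, times, events, ties="efron")
        ref = CoxPHFitter().fit(
            X.assign(T=times, E=events.astype(int)), "T", "E")
        for col in ("x", "z"):
            assert fit[col].coef == pytest.approx(ref.params_[col], abs=5e-4)
            assert fit[col].se == pytest.approx(ref.standard_errors_[col],
                                                abs=5e-4)

    def test_loglik_never_decreases(self):
        X, times, events = two_arm(5, n=120, ties=True)
        fit = cox_fit(X, times, events)
        assert all(b >= a - 1e-9 for a, b in zip(fit.loglik_trace,
                                                 fit.loglik_trace[1:]))

    def test_complete_separation_named(self):
        # the covariate perfectly orders the deaths: monotone likelihood
        times = np.arange(1.0, 21.0)
        events = np.ones(20, bool)
        X = pd.DataFrame({"sep": -times})
        with pytest.raises(ConvergenceError, match="sep"):
            cox_fit(X, times, events)

    def test_constant_covariate_named(self):
        X = pd.DataFrame({"flat": np.ones(10)})
        with pytest.raises(ValidationError, match="flat"):
            cox_fit(X, np.arange(1.0, 11.0), np.ones(10, bool))

    def test_complete_cases_counted(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 0.0, 1.0, 0.0, 1.0]})
        fit = cox_fit(X, np.arange(1.0, 7.0), np.ones(6, bool))
        assert fit.n == 5 and fit.n_dropped == 1

    def test_wald_ci_brackets_hr(self):
        X, times, events = two_arm(6)
        fit = cox_fit(X, times, events)
        term = fit["x"]
        assert term.ci_low <= term.hr <= term.ci_high
        assert term.hr == pytest.approx(np.exp(term.coef))


class TestBackwardSelect:
    def _nulls(self, seed, k=5, n=300):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({f"v{i}": rng.normal(size=n) for i in range(k)})
        times = rng.exponential(10.0, size=n)
        return X, times, np.ones(n, bool)

    def test_retain_p_one_keeps_full_model(self):
        X, times, events = self._nulls(0)
        sel = backward_select(X, times, events, retain_p=1.0)
        assert sel.retained == list(X.columns)
        assert sel.dropped == []

    def test_null_covariates_mostly_dropped(self):
        dropped_counts = [
            len(backward_select(*self._nulls(seed), retain_p=0.05).dropped)
            for seed in range(10)
        ]
        # ~ alpha false retention per variable: nearly all of 5 nulls go
        assert np.mean(dropped_counts) >= 4.0

    def test_strong_covariate_retained(self):
        retained = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            x = rng.integers(0, 2, n).astype(float)
            X = pd.DataFrame({"real": x,
                              "junk1": rng.normal(size=n),
                              "junk2": rng.normal(size=n)})
            times = rng.exponential(1.0 / (0.05 * np.exp(0.9 * x)))
            sel = backward_select(X, times, np.ones(n, bool), retain_p=0.05)
            retained += "real" in sel.retained
        assert retained >= 19

    def test_force_in_survives_elimination(self):
        X, times, events = self._nulls(1)
        sel = backward_select(X, times, events, retain_p=0.05,
                              force_in=("v0",))
        assert "v0" in sel.retained


class TestInteractionAnalysis:
    def _cohort(self, seed, n=300):
        rng = np.random.default_rng(seed)
        labels = np.array(["INT", "COD"])[rng.integers(0, 2, n)]
        cfg = SimulationConfig(seed=seed)
        times, events, chemo = simulate_survival(labels, cfg, rng=rng)
        return labels, chemo, times, events

    def test_recovers_differential_benefit(self):
        hr_cod, hr_int = [], []
        for seed in range(30):
            labels, chemo, times, events = self._cohort(seed, n=500)
            res = interaction_analysis(labels, chemo, times, events)
            hr_cod.append(res.stratum_hr("COD"))
            hr_int.append(res.stratum_hr("INT"))
        assert np.median(hr_cod) == pytest.approx(0.333, abs=0.1)
        assert np.median(hr_int) == pytest.approx(0.576, abs=0.1)

    def test_untreated_stratum_flagged_absent(self):
        labels, chemo, times, events = self._cohort(1)
        chemo = chemo & (labels == "COD")  # nobody treated in INT
        res = interaction_analysis(labels, chemo, times, events)
        assert res.stratum_models["INT"] is None
        assert res.stratum_models["COD"] is not None
        assert res.interaction_model is None
        assert "cells" in (res.error or "")

    def test_interaction_term_reported(self):
        labels, chemo, times, events = self._cohort(2, n=400)
        res = interaction_analysis(labels, chemo, times, events)
        assert res.interaction_model is not None
        assert 0.0 <= res.interaction_p <= 1.0

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValidationError):
            interaction_analysis(["A", "B"], [True, False], [1.0, 2.0],
                                 [True, True])
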