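"""Likelihood oracles, closed forms, nesting identities and fit behaviour."""

import numpy as np
import pytest
from statsmodels.tools import numdiff

from pemfrail import (Cohort, ExponentialHazard, MissingCovariateError,
                      PieceGrid, PiecewiseExponentialHazard,
                      SimulationDesign, WeibullHazard, fit_pem_poisson,
                      loglik_frailty, loglik_independence, simulate_cohort,
                      split_at_cuts)
from pemfrail.models import _EpisodeArrays

from conftest import make_cohort

COV = ("male", "age", "union", "smelter", "physical_demand")


class TestIndependenceLoglik:
    def test_exponential_closed_form_single_episode(self):
        """(0,10], event, lam=0.1: loglik = log(0.1) - 1.0."""
        c = make_cohort([("s1", "j1", 0.0, 10.0, 1)])
        ll = loglik_independence(ExponentialHazard(), [np.log(0.1)], c)
        assert ll == pytest.approx(np.log(0.1) - 1.0, abs=1e-12)

    def test_weibull_shape_one_equals_exponential(self, small_cohort):
        cohort, _ = small_cohort
        lam = np.log(0.03)
        ll_e = loglik_independence(ExponentialHazard(covariates=COV),
                                   [lam, 0.1, 0.2, 0, 0, -0.1], cohort)
        ll_w = loglik_independence(WeibullHazard(covariates=COV),
                                   [lam, 0.0, 0.1, 0.2, 0, 0, -0.1], cohort)
        assert ll_w == pytest.approx(ll_e, rel=1e-12)

    def test_pem_equal_rates_equals_exponential(self, small_cohort):
        cohort, _ = small_cohort
        lam = np.log(0.03)
        ll_e = loglik_independence(ExponentialHazard(), [lam], cohort)
        ll_p = loglik_independence(
            PiecewiseExponentialHazard(cuts=(6.0, 12.0, 24.0)),
            [lam, 0.0, 0.0, 0.0], cohort)
        assert ll_p == pytest.approx(ll_e, rel=1e-12)


class TestExponentialFit:
    def test_mle_is_events_over_persontime(self, plain_cohort):
        fit = ExponentialHazard().fit(plain_cohort)
        assert fit.rate_ == pytest.approx(
            plain_cohort.n_events / plain_cohort.person_time, abs=1e-10)

    def test_score_zero_at_mle(self, plain_cohort):
        fit = ExponentialHazard().fit(plain_cohort)
        arr = _EpisodeArrays(plain_cohort, ())
        g = fit._grad_arrays(fit.params_, arr, frailty=False)
        assert np.abs(g).max() < 1e-7 * abs(fit.loglik_)

    def test_zero_events_boundary_with_warning(self):
        c = make_cohort([("s1", "j1", 0.0, 10.0, 0)])
        with pytest.warns(UserWarning, match="no events"):
            fit = ExponentialHazard().fit(c)
        assert fit.loglik_ == 0.0


class TestPemFit:
    def test_per_piece_closed_form(self, plain_cohort):
        fit = PiecewiseExponentialHazard(cuts=(12.0,)).fit(plain_cohort)
        rows = split_at_cuts(plain_cohort, PieceGrid((12.0,)))
        g = rows.groupby("piece")
        expected = (g["events"].sum() / g["exposure"].sum()).to_numpy()
        np.testing.assert_allclose(fit.piece_rates_, expected, rtol=1e-7)

    def test_poisson_route_matches_direct(self, small_cohort):
        cohort, _ = small_cohort
        rows = split_at_cuts(cohort, PieceGrid((12.0,)))
        via_glm = fit_pem_poisson(rows, COV, cuts=(12.0,))
        direct = PiecewiseExponentialHazard(cuts=(12.0,), covariates=COV).fit(cohort)
        np.testing.assert_allclose(via_glm.params_, direct.params_, atol=1e-6)
        assert via_glm.loglik_ == pytest.approx(direct.loglik_, abs=1e-6)

    def test_poisson_intercepts_reproduce_piece_rates(self, plain_cohort):
        rows = split_at_cuts(plain_cohort, PieceGrid((12.0,)))
        fit = fit_pem_poisson(rows, (), cuts=(12.0,))
        g = rows.groupby("piece")
        rates = (g["events"].sum() / g["exposure"].sum()).to_numpy()
        # reference is the last piece; the dummy is the early-piece log HR
        assert np.exp(fit.params_[0]) == pytest.approx(rates[1], rel=1e-8)
        assert np.exp(fit.params_[0] + fit.params_[1]) == pytest.approx(
            rates[0], rel=1e-8)

    def test_missing_covariates_rejected(self, small_cohort):
        cohort, _ = small_cohort
        data = cohort.data.copy()
        data.loc[data.index[0], "physical_demand"] = np.nan
        broken = Cohort(data, list(cohort.covariates))
        with pytest.raises(MissingCovariateError, match="impute"):
            PiecewiseExponentialHazard(covariates=COV).fit(broken)


class TestNesting:
    def test_maximized_logliks_nested_order(self, small_cohort):
        cohort, _ = small_cohort
        ll_e = ExponentialHazard(covariates=COV).fit(cohort).loglik_
        ll_w = WeibullHazard(covariates=COV).fit(cohort).loglik_
        ll_p = PiecewiseExponentialHazard(cuts=(12.0,), covariates=COV).fit(cohort).loglik_
        assert ll_w >= ll_e - 1e-8
        assert ll_p >= ll_e - 1e-8


class TestFrailtyLoglik:
    def test_single_censored_subject_closed_form(self):
        """One censored episode: loglik = -(1/theta) log(1 + theta*H)."""
        c = make_cohort([("s1", "j1", 0.0, 10.0, 0)])
        lam, theta = 0.05, 0.7
        ll = loglik_frailty(ExponentialHazard(), [np.log(lam)], theta, c)
        assert ll == pytest.approx(-np.log1p(theta * lam * 10) / theta, abs=1e-12)

    def test_theta_zero_limit_is_independence(self, plain_cohort):
        sub = plain_cohort.subset_subjects(plain_cohort.subject_ids()[:100])
        model = ExponentialHazard()
        ll_ind = loglik_independence(model, [np.log(0.03)], sub)
        ll_fr = loglik_frailty(model, [np.log(0.03)], 1e-8, sub)
        assert ll_fr == pytest.approx(ll_ind, abs=1e-4)

    def test_theta_nonpositive_rejected(self, plain_cohort):
        with pytest.raises(ValueError):
            loglik_frailty(ExponentialHazard(), [np.log(0.03)], 0.0, plain_cohort)

    def test_gradient_matches_numeric(self, small_cohort):
        cohort, _ = small_cohort
        model = PiecewiseExponentialHazard(cuts=(12.0,), covariates=COV,
                                           frailty=True)
        arr = _EpisodeArrays(cohort, COV)
        q = np.concatenate([model._base_start(arr), np.full(5, 0.05),
                            [np.log(0.4)]])
        g = model._grad_arrays(q, arr, frailty=True)
        g_num = numdiff.approx_fprime(
            q, lambda z: model._loglik_arrays(z, arr, True), centered=True)
        np.testing.assert_allclose(g, g_num, atol=1e-4 * (1 + np.abs(g).max()))

    def test_theta_recovered_on_simulated_data(self):
        d = SimulationDesign(n_subjects=4000, seed=13, beta={},
                             covariate_generators={}, frailty_variance=0.5)
        c, _ = simulate_cohort(d)
        fit = ExponentialHazard(frailty=True).fit(c)
        assert fit.converged_
        assert fit.theta_ == pytest.approx(0.5, abs=3 * fit.theta_se_)


class TestPredictSurvival:
    def test_survival_starts_at_one(self, plain_cohort):
        fit = PiecewiseExponentialHazard(cuts=(12.0,)).fit(plain_cohort)
        assert fit.predict_survival(times=[0.0])[0] == 1.0

    def test_exponential_value(self, plain_cohort):
        fit = ExponentialHazard().fit(plain_cohort)
        lam = fit.rate_
        s = fit.predict_survival(times=[10.0])[0]
        assert s == pytest.approx(np.exp(-lam * 10.0), rel=1e-10)

    def test_pem_curve_piecewise_loglinear_kink_at_cut(self, plain_cohort):
        fit = PiecewiseExponentialHazard(cuts=(12.0,)).fit(plain_cohort)
        t = np.array([0.0, 6.0, 12.0, 18.0, 24.0])
        logS = np.log(fit.predict_survival(times=t))
        slopes = np.diff(logS) / np.diff(t)
        np.testing.assert_allclose(slopes[0], slopes[1], rtol=1e-9)
        np.testing.assert_allclose(slopes[2], slopes[3], rtol=1e-9)
        np.testing.assert_allclose(-slopes[1], fit.piece_rates_[0], rtol=1e-9)
        np.testing.assert_allclose(-slopes[2], fit.piece_rates_[1], rtol=1e-9)

    def test_population_curve_heavier_tail(self):
        d = SimulationDesign(n_subjects=2000, seed=14, beta={},
                             covariate_generators={}, frailty_variance=0.8)
        c, _ = simulate_cohort(d)
        fit = ExponentialHazard(frailty=True).fit(c)
        t = [5.0, 20.0, 40.0]
        cond = fit.predict_survival(times=t, kind="conditional")
        pop = fit.predict_survival(times=t, kind="population")
        assert (pop > cond).all()

    def test_unknown_covariate_rejected(self, plain_cohort):
        fit = ExponentialHazard().fit(plain_cohort)
        with pytest.raises(KeyError):
            fit.predict_survival(covariates={"nope": 1.0}, times=[1.0])


class TestHazardRatioTable:
    def test_unit_normal_coefficient_ci(self, plain_cohort):
        fit = ExponentialHazard(covariates=()).fit(plain_cohort)
        fit.covariates = ("x",)
        fit.params_ = np.array([np.log(0.03), 0.0])
        fit.se_ = __import__("pandas").Series([0.1, 1.0],
                                              index=["log_rate", "x"])
        tab = fit.hazard_ratio_table()
        assert tab.loc[0, "hr"] == pytest.approx(1.0)
        assert tab.loc[0, "ci_low"] == pytest.approx(0.1408, abs=5e-4)
        assert tab.loc[0, "ci_high"] == pytest.approx(7.099, abs=5e-3)

    def test_ci_width_monotone_in_se(self):
        import pandas as pd
        fit = ExponentialHazard(covariates=("x",))
        fit.params_ = np.array([0.0, np.log(1.32)])
        widths = []
        for se in (0.01, 0.05, 0.2):
            fit.se_ = pd.Series([0.1, se], index=["log_rate", "x"])
            t = fit.hazard_ratio_table()
            widths.append(t.loc[0, "ci_high"] - t.loc[0, "ci_low"])
            assert t.loc[0, "hr"] == pytest.approx(1.32)
        assert widths == sorted(widths)

    def test_pem_reports_inexperienced_period_hr(self, small_cohort):
        cohort, _ = small_cohort
        fit = PiecewiseExponentialHazard(cuts=(12.0,), covariates=COV).fit(cohort)
        tab = fit.hazard_ratio_table()
        assert tab.loc[0, "term"].startswith("piece (0,12]")
        assert tab.loc[0, "hr"] == pytest.approx(
            fit.piece_rates_[0] / fit.piece_rates_[1], rel=1e-7)
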