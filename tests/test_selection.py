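"""Partitioning, LRT / BIC / Bayes factors, KM diagnostics and the pipeline."""

import numpy as np
import pytest

from pemfrail import (ComparisonTable, ExponentialHazard, PipelineConfig,
                      PiecewiseExponentialHazard, SimulationDesign,
                      WeibullHazard, bayes_factor, bic, km_curve, lrt,
                      run_selection_pipeline, simulate_cohort,
                      simulate_weibull_cohort, split_learning_test)
from pemfrail.selection import effective_n

from conftest import make_cohort


class TestSplit:
    def test_three_employees_two_thirds(self):
        c = make_cohort([("s1", "j1", 0.0, 5.0, 0), ("s2", "j1", 0.0, 5.0, 0),
                         ("s3", "j1", 0.0, 5.0, 0)])
        learn, test = split_learning_test(c, 2.0 / 3.0, seed=0)
        assert learn.n_subjects == 2 and test.n_subjects == 1

    def test_partition_is_exact_and_by_employee(self, small_cohort):
        cohort, _ = small_cohort
        learn, test = split_learning_test(cohort, seed=1)
        l_ids = set(learn.subject_ids())
        t_ids = set(test.subject_ids())
        assert l_ids.isdisjoint(t_ids)
        assert l_ids | t_ids == set(cohort.subject_ids())
        assert learn.n_episodes + test.n_episodes == cohort.n_episodes

    def test_deterministic(self, small_cohort):
        cohort, _ = small_cohort
        a, _ = split_learning_test(cohort, seed=5)
        b, _ = split_learning_test(cohort, seed=5)
        assert list(a.subject_ids()) == list(b.subject_ids())


class TestLrt:
    def test_identical_fits_statistic_zero(self, plain_cohort):
        f = ExponentialHazard().fit(plain_cohort)
        stat, df, p = lrt(f, f)
        assert stat == 0.0 and p == 1.0

    def test_exponential_vs_weibull_df_one(self, small_cohort):
        cohort, _ = small_cohort
        cov = tuple(cohort.covariates)
        e = ExponentialHazard(covariates=cov).fit(cohort)
        w = WeibullHazard(covariates=cov).fit(cohort)
        stat, df, p = lrt(e, w)
        assert df == 1
        assert e.n_params_ == 6 and w.n_params_ == 7

    def test_reversed_fits_raise(self, plain_cohort):
        e = ExponentialHazard().fit(plain_cohort)
        p2 = PiecewiseExponentialHazard(cuts=(12.0,)).fit(plain_cohort)
        if p2.loglik_ > e.loglik_ + 1e-6:
            with pytest.raises(RuntimeError, match="fitting failure"):
                lrt(p2, e)


class TestBicBayes:
    def test_bic_arithmetic(self):
        class F:
            loglik_, n_params_ = -100.0, 2
        assert bic(F(), 50) == pytest.approx(200 + 2 * np.log(50), abs=1e-9)

    def test_bic_monotone_in_loglik(self):
        class F:
            n_params_ = 3
        a, b = F(), F()
        a.loglik_, b.loglik_ = -90.0, -100.0
        assert bic(a, 100) < bic(b, 100)

    def test_bayes_factor_reciprocity_and_scale(self, plain_cohort):
        e = ExponentialHazard().fit(plain_cohort)
        w = WeibullHazard().fit(plain_cohort)
        n = effective_n(e, "events")
        assert bayes_factor(e, e, n) == 1.0
        assert bayes_factor(e, w, n) * bayes_factor(w, e, n) == pytest.approx(1.0)

    def test_delta_bic_two_gives_bf_e(self):
        class F:
            n_params_ = 2
        a, b = F(), F()
        a.loglik_, b.loglik_ = -99.5, -100.5  # delta BIC = -2 in favour of a
        assert bayes_factor(a, b, 50) == pytest.approx(np.e)

    def test_bic_prefers_two_piece_under_two_piece_truth(self):
        design = SimulationDesign(n_subjects=10_000, seed=21, cuts=(12.0,),
                                  piece_rates=(0.04, 0.02), beta={},
                                  covariate_generators={}, frailty_variance=0.0)
        c, _ = simulate_cohort(design)
        fits = {
            "exponential": ExponentialHazard().fit(c),
            "weibull": WeibullHazard().fit(c),
            "pem": PiecewiseExponentialHazard(cuts=(12.0,)).fit(c),
        }
        n = effective_n(fits["exponential"], "events")
        bics = {k: bic(f, n) for k, f in fits.items()}
        assert bics["pem"] < bics["weibull"]
        assert bics["pem"] < bics["exponential"]


class TestKm:
    def test_product_limit_by_hand(self):
        c = make_cohort([("s1", "j1", 0.0, 1.0, 1), ("s2", "j1", 0.0, 2.0, 1),
                         ("s3", "j1", 0.0, 3.0, 1)])
        t = km_curve(c)
        s = t.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[2.0] == pytest.approx(1 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_mixed_censoring_by_hand(self):
        # events at 1 and 3, censored at 2: S(1)=3/4, S(3)=3/8
        c = make_cohort([("s1", "j1", 0.0, 1.0, 1), ("s2", "j1", 0.0, 2.0, 0),
                         ("s3", "j1", 0.0, 3.0, 1), ("s4", "j1", 0.0, 4.0, 0)])
        t = km_curve(c)
        s = t.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(3 / 4)
        assert s.loc[3.0] == pytest.approx(3 / 8)

    def test_all_censored_survival_one(self):
        c = make_cohort([("s1", "j1", 0.0, 5.0, 0), ("s2", "j1", 0.0, 9.0, 0)])
        t = km_curve(c)
        assert (t["survival"] == 1.0).all()

    def test_loglog_slope_recovers_weibull_shape(self):
        shape = 1.4
        c = simulate_weibull_cohort(5000, rate=0.01, shape=shape,
                                    censor_time=60.0, seed=31)
        t = km_curve(c)
        pts = t[(t["survival"] > 0.01) & (t["survival"] < 0.99)
                & np.isfinite(t["loglog"])]
        slope = np.polyfit(pts["log_time"], pts["loglog"], 1)[0]
        assert slope == pytest.approx(shape, rel=0.10)


class TestComparisonTable:
    def make_table(self, plain_cohort):
        fits = {
            "exponential": ExponentialHazard().fit(plain_cohort),
            "weibull": WeibullHazard().fit(plain_cohort),
            "pem_hypothesis": PiecewiseExponentialHazard(cuts=(12.0,)).fit(plain_cohort),
            "pem_datadriven": PiecewiseExponentialHazard(cuts=(19.0,)).fit(plain_cohort),
        }
        return ComparisonTable(fits, n=fits["exponential"].n_events_)

    def test_refuses_two_piece_pair(self, plain_cohort):
        tab = self.make_table(plain_cohort)
        with pytest.raises(ValueError, match="not compared"):
            tab.compare("pem_hypothesis", "pem_datadriven")

    def test_no_lrt_for_weibull_vs_pem(self, plain_cohort):
        tab = self.make_table(plain_cohort)
        pairs = tab.all_pairs()
        row = pairs[(pairs["a"] == "weibull") & (pairs["b"] == "pem_hypothesis")]
        assert row["kind"].iloc[0] == "bic"
        lrt_rows = pairs[pairs["kind"] == "lrt"]
        assert set(lrt_rows["a"]) == {"exponential"}


@pytest.fixture(scope="module")
def pipeline_run():
    design = SimulationDesign(n_subjects=2500, seed=17, cuts=(12.0,),
                              piece_rates=(0.03, 0.02))
    cohort, _ = simulate_cohort(design)
    cfg = PipelineConfig(covariates=tuple(cohort.covariates),
                         candidates=tuple(np.arange(3.0, 36.0)),
                         bootstrap_B=15, bootstrap_sample_size=400,
                         mi_m=2, seed=2)
    return cohort, cfg, run_selection_pipeline(cohort, cfg)


class TestPipeline:
    def test_emits_comparison_shaped_output(self, pipeline_run):
        _, _, res = pipeline_run
        stats = res.table.fit_stats()
        assert set(stats["model"]) == {"exponential", "weibull",
                                       "pem_hypothesis", "pem_datadriven"}
        assert {"loglik", "n_params", "bic"} <= set(stats.columns)
        assert res.bootstrap.B == 15

    def test_tau_from_learning_set_only(self, pipeline_run):
        cohort, cfg, res = pipeline_run
        learn, _ = split_learning_test(cohort, cfg.learn_fraction,
                                       seed=res.log["seeds"]["split"])
        from pemfrail import profile_changepoint
        est = profile_changepoint(learn, candidates=cfg.candidates,
                                  covariates=cfg.covariates,
                                  min_events=cfg.min_events)
        assert est.tau_hat == res.changepoint.tau_hat

    def test_deterministic_given_seed(self, pipeline_run):
        cohort, cfg, res = pipeline_run
        res2 = run_selection_pipeline(cohort, cfg)
        assert res2.changepoint.tau_hat == res.changepoint.tau_hat
        np.testing.assert_array_equal(res2.bootstrap.replicates,
                                      res.bootstrap.replicates)
        assert res2.table.fit_stats().equals(res.table.fit_stats())

    def test_no_missingness_skips_mi(self, pipeline_run):
        _, _, res = pipeline_run
        for entry in res.final_fits.values():
            assert "mi" not in entry
            assert entry["cc"].theta_ > 0  # frailty fit on the full cohort
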