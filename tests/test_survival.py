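import numpy as np
import pytest

from ihcsub.errors import FieldRangeError
from ihcsub.survival import (
    Ties,
    cox_fit,
    gehan_wilcoxon_test,
    km_estimate,
    logrank_test,
    run_survival_analysis,
)


class TestKaplanMeier:
    def test_all_censored_constant_one(self):
        curve = km_estimate([5, 10, 15], [False, False, False])
        assert curve.times.size == 0
        assert curve.at(100) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [True, False, True])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2) == pytest.approx(2 / 3)  # censoring: no drop
        assert curve.at(3) == pytest.approx(0.0)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 50, 20).astype(float)
        e = rng.random(20) < 0.6
        base = km_estimate(t, e)
        doubled = km_estimate(np.r_[t, t], np.r_[e, e])
        assert np.allclose(base.survival, doubled.survival)
        assert np.array_equal(base.times, doubled.times)

    def test_negative_time_rejected(self):
        with pytest.raises(FieldRangeError):
            km_estimate([-1.0], [True])

    def test_random_inputs_bounds_and_monotonicity(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(1, 40))
            t = rng.exponential(100, n)
            e = rng.random(n) < rng.random()
            curve = km_estimate(t, e)
            if curve.survival.size:
                assert curve.survival.max() <= 1 + 1e-12
                assert curve.survival.min() >= -1e-12
                assert np.all(np.diff(curve.survival) <= 1e-12)


class TestLogrank:
    def test_identical_groups(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([True, True, False, True, False])
        chi2, df, p = logrank_test([(t, e), (t, e)])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_two_group(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(4)
        t1 = np.round(rng.exponential(100, 60)) + 1
        t2 = np.round(rng.exponential(160, 50)) + 1
        e1 = rng.random(60) < 0.75
        e2 = rng.random(50) < 0.75
        chi2, _, p = logrank_test([(t1, e1), (t2, e2)])
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)
        assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_matches_lifelines_three_group(self):
        import pandas as pd
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(6)
        t = np.round(rng.exponential(100, 90)) + 1
        e = rng.random(90) < 0.7
        g = rng.integers(0, 3, 90)
        groups = [(t[g == i], e[g == i]) for i in range(3)]
        chi2, df, p = logrank_test(groups)
        ref = multivariate_logrank_test(t, g, e)
        assert df == 2
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(FieldRangeError):
            logrank_test([(np.array([1.0]), np.array([True])),
                          (np.array([]), np.array([]))])

    def test_relabel_invariance(self):
        rng = np.random.default_rng(8)
        groups = [(rng.exponential(100, 30), rng.random(30) < 0.7)
                  for _ in range(3)]
        base = logrank_test(groups)
        shuffled = logrank_test([groups[2], groups[0], groups[1]])
        assert base[0] == pytest.approx(shuffled[0], abs=1e-10)


class TestGehanWilcoxon:
    def test_identical_groups(self):
        t = np.array([1.0, 2, 3])
        e = np.array([True, True, True])
        _, _, p = gehan_wilcoxon_test([(t, e), (t, e)])
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_wilcoxon_weighting(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(9)
        t1 = np.round(rng.exponential(80, 40)) + 1
        t2 = np.round(rng.exponential(140, 40)) + 1
        e1 = rng.random(40) < 0.8
        e2 = rng.random(40) < 0.8
        chi2, _, _ = gehan_wilcoxon_test([(t1, e1), (t2, e2)])
        ref = ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2,
                         weightings="wilcoxon")
        assert chi2 == pytest.approx(ref.test_statistic, abs=1e-8)

    def test_early_separation_favors_wilcoxon(self):
        # curves separate early then converge: the at-risk-weighted test
        # should see it more clearly than the plain log-rank
        t1 = np.array([1, 2, 3, 4, 5, 30, 31, 32, 33, 34], dtype=float)
        t2 = np.array([10, 11, 12, 13, 14, 30, 31, 32, 33, 34], dtype=float)
        e = np.ones(10, dtype=bool)
        _, _, p_lr = logrank_test([(t1, e), (t2, e)])
        _, _, p_wx = gehan_wilcoxon_test([(t1, e), (t2, e)])
        assert p_wx < p_lr


class TestCoxFit:
    def _simulate(self, rng, n, log_hr, censor_rate=0.0025):
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.01 * np.exp(log_hr * x)))
        c = rng.exponential(1 / censor_rate, n)
        return x, np.minimum(t, c), t <= c

    def test_null_recovery(self):
        rng = np.random.default_rng(100)
        x, t, e = self._simulate(rng, 2000, 0.0)
        fit = cox_fit(x, t, e)
        assert fit.converged
        assert abs(fit.coef[0]) < 0.1

    def test_log2_recovery(self):
        rng = np.random.default_rng(101)
        x, t, e = self._simulate(rng, 2000, np.log(2))
        fit = cox_fit(x, t, e)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(np.log(2), abs=0.1)
        assert fit.hr[0] == pytest.approx(np.exp(fit.coef[0]))
        assert fit.ci_low[0] == pytest.approx(
            np.exp(fit.coef[0] - 1.959963984540054 * fit.se[0]))

    def test_efron_breslow_agree_without_ties(self):
        rng = np.random.default_rng(102)
        n = 150
        x = rng.normal(size=n)
        t = rng.exponential(1 / (0.01 * np.exp(0.4 * x)))  # continuous: no ties
        e = rng.random(n) < 0.8
        fe = cox_fit(x, t, e, ties=Ties.EFRON)
        fb = cox_fit(x, t, e, ties=Ties.BRESLOW)
        assert fe.coef[0] == pytest.approx(fb.coef[0], abs=1e-6)

    def test_matches_lifelines(self):
        import pandas as pd
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(103)
        n = 250
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        t = np.round(rng.exponential(1 / (0.01 * np.exp(0.5 * x1 - 0.3 * x2)))) + 1
        e = rng.random(n) < 0.7
        fit = cox_fit(np.c_[x1, x2], t, e, names=("x1", "x2"))
        df = pd.DataFrame({"t": t, "e": e.astype(int), "x1": x1, "x2": x2})
        ref = CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.coef, ref.params_.values, atol=1e-5)
        assert np.allclose(fit.se, ref.standard_errors_.values, atol=1e-5)

    def test_constant_covariate_rejected(self):
        with pytest.raises(FieldRangeError):
            cox_fit(np.ones(10), np.arange(1.0, 11.0), np.ones(10, dtype=bool))

    def test_separation_flags_divergence(self):
        # perfect separation: all events in x=1 before any x=0 subject
        t = np.r_[np.arange(1.0, 11.0), np.arange(100.0, 110.0)]
        x = np.r_[np.ones(10), np.zeros(10)]
        e = np.ones(20, dtype=bool)
        fit = cox_fit(x, t, e)
        assert not fit.converged


class TestRunSurvivalAnalysis:
    def test_pattern_report(self, default_synthetic_cohort):
        report = run_survival_analysis(default_synthetic_cohort)
        assert set(report["groups"]) == {"classical", "transitional",
                                         "basal_like"}
        assert report["logrank"]["p"] < 0.05
        multi = {c["covariate"]: c for c in
                 report["multivariate"]["covariates"]}
        # the generator injects HR 1.9 / 3.5 for transitional/basal
        assert multi["expression_type"]["hr"] > 1

    def test_univariate_expression_type_near_injected_hr(
            self, default_synthetic_cohort):
        report = run_survival_analysis(default_synthetic_cohort)
        uni = report["univariate"]["expression_type"]["covariates"][0]
        assert 1.0 < uni["hr"] < 4.0

    def test_stage_models_drop_unknown(self, default_synthetic_cohort):
        report = run_survival_analysis(default_synthetic_cohort)
        n_unknown = sum(1 for c in default_synthetic_cohort
                        if c.stage.value == "NA")
        assert report["multivariate"]["n"] == (
            len(default_synthetic_cohort) - n_unknown)
        assert report["univariate"]["sex_male"]["n"] == len(
            default_synthetic_cohort)

    def test_ck56_glandular_subgroup(self, default_synthetic_cohort):
        report = run_survival_analysis(default_synthetic_cohort,
                                       grouping="ck56_pos",
                                       glandular_only=True)
        n_total = sum(v["n"] for v in report["groups"].values())
        n_glandular = sum(1 for c in default_synthetic_cohort
                          if c.histology.value == "glandular")
        assert n_total == n_glandular
        assert set(report["groups"]) == {"negative", "positive"}

    def test_null_grouping_logrank_uniform(self):
        # grouping by a coin: p-values should look uniform over seeds
        from scipy.stats import kstest

        from ihcsub.synthdata import CohortSimConfig, generate_cohort

        pvals = []
        for seed in range(60):
            c = generate_cohort(CohortSimConfig(seed=seed, n=120,
                                                quotas=None,
                                                hazard_ratios=(1, 1, 1)))
            rng = np.random.default_rng(seed + 1000)
            coin = rng.random(len(c)) < 0.5
            t = np.array([x.time_days for x in c])
            e = np.array([x.event for x in c])
            _, _, p = logrank_test([(t[coin], e[coin]), (t[~coin], e[~coin])])
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01
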