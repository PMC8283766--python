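import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from exonskip.simulate import CohortSimConfig, simulate_cohort
from exonskip.survival import (
    SurvivalError,
    cox_fit,
    cox_score_test,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    marker_cell,
    pearson_corr,
    table1_report,
    truncate_followup,
)


class TestKaplanMeier:
    def test_all_censored_flat_at_one(self):
        km = km_estimate([5, 7, 9], [0, 0, 0])
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_three_events_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert km.at_risk.tolist() == [3, 2, 1]

    def test_single_event_half(self):
        km = km_estimate([5, 10], [1, 0])
        assert km.survival_at(5) == pytest.approx(0.5)

    def test_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 100)
        e = rng.integers(0, 2, 100)
        if e.sum() == 0:
            e[0] = 1
        km = km_estimate(t, e)
        assert km.survival_at(-1e-9) == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, 200)
        km = km_estimate(t, np.ones(200, dtype=int))
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(t > et))

    def test_negative_time_rejected(self):
        with pytest.raises(SurvivalError):
            km_estimate([-1, 2], [1, 1])

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(2)
        t = np.round(rng.exponential(10, 150), 1)  # rounding induces ties
        e = (rng.random(150) < 0.7).astype(int)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(km.times, km.survival):
            assert s == pytest.approx(kmf.predict(et), rel=1e-9)


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        res = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_worked_example(self):
        # group A events at 1 and 2; group B censored at 3 and 4.
        # risk tables: t=1: nA=2,nB=2,d=1 -> E_A=1/2, V=1/4
        #              t=2: nA=1,nB=2,d=1 -> E_A=1/3, V=2/9
        # chi2 = (2 - 5/6)^2 / (17/36) = 49/17
        res = logrank_test([1, 2, 3, 4], [1, 1, 0, 0], ["A", "A", "B", "B"])
        assert res.chi2 == pytest.approx(49 / 17, rel=1e-12)
        assert res.df == 1

    def test_three_identical_groups(self):
        t = [1, 2, 3]
        e = [1, 1, 1]
        res = logrank_test(t * 3, e * 3, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.df == 2
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_time_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 80)
        e = (rng.random(80) < 0.8).astype(int)
        g = rng.integers(0, 2, 80)
        r1 = logrank_test(t, e, g)
        r2 = logrank_test(t * 12.0, e, g)
        assert r1.chi2 == pytest.approx(r2.chi2, rel=1e-12)

    def test_matches_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(4)
        n = 120
        g = rng.integers(0, 3, n)
        t = rng.exponential(10 / (1 + g), n)
        e = (rng.random(n) < 0.8).astype(int)
        mine = logrank_test(t, e, g)
        ref = multivariate_logrank_test(t, g, e)
        assert mine.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2], [1, 1], ["a", "a"])

    def test_no_events_rejected(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2], [0, 0], ["a", "b"])


class TestCox:
    def _sim(self, n=400, hr=2.0, seed=0, censor=0.3):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.05 * hr**x))
        c = rng.exponential(t.mean() / censor * 2, n)
        e = (t <= c).astype(int)
        return np.minimum(t, c), e, x

    def test_null_hr_close_to_one(self):
        t, e, x = self._sim(n=2000, hr=1.0, seed=1)
        res = cox_fit(t, e, {"x": x})
        c = res["x"]
        assert c.ci_low < 1.0 < c.ci_high
        assert abs(c.coef) < 0.2

    def test_recovers_true_hr(self):
        t, e, x = self._sim(n=2000, hr=3.0, seed=2)
        res = cox_fit(t, e, {"x": x})
        assert res["x"].hr == pytest.approx(3.0, rel=0.15)

    def test_ci_ordering(self):
        t, e, x = self._sim(seed=3)
        c = cox_fit(t, e, {"x": x})["x"]
        assert c.ci_low <= c.hr <= c.ci_high

    def test_all_censored_low_group_is_na_with_reason(self):
        # events only in the high group, none in the low group -> separation
        t = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        x = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        res = cox_fit(t, e, {"x": x})
        assert res.is_na
        assert "monotone" in res.na_reason

    def test_constant_covariate_rejected(self):
        with pytest.raises(SurvivalError):
            cox_fit([1, 2, 3], [1, 1, 0], {"x": [1.0, 1.0, 1.0]})

    def test_no_events_rejected(self):
        with pytest.raises(SurvivalError):
            cox_fit([1, 2], [0, 0], {"x": [0.0, 1.0]})

    def test_matches_lifelines_univariate(self):
        from lifelines import CoxPHFitter

        t, e, x = self._sim(n=300, hr=2.0, seed=5)
        t = np.round(t, 1)  # force ties to exercise the Efron path
        res = cox_fit(t, e, {"x": x})
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        cph = CoxPHFitter().fit(df, "t", "e")
        assert res["x"].coef == pytest.approx(cph.params_["x"], rel=1e-5, abs=1e-8)
        assert res["x"].se == pytest.approx(cph.standard_errors_["x"], rel=1e-4)

    def test_matches_lifelines_multivariate(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(6)
        n = 250
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x1 + 0.3 * x2)))
        e = (rng.random(n) < 0.75).astype(int)
        res = cox_fit(t, e, {"x1": x1, "x2": x2})
        df = pd.DataFrame({"t": t, "e": e, "x1": x1, "x2": x2})
        cph = CoxPHFitter().fit(df, "t", "e")
        for name in ("x1", "x2"):
            assert res[name].coef == pytest.approx(cph.params_[name], rel=1e-5, abs=1e-8)
            assert res[name].p == pytest.approx(cph.summary.loc[name, "p"], rel=1e-3)

    def test_score_test_equals_logrank_on_tie_free_data(self):
        rng = np.random.default_rng(7)
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(0.5 * x)))  # continuous: no ties
        e = np.ones(n, dtype=int)
        assert np.unique(t).size == n
        chi2, df, p = cox_score_test(t, e, {"x": x})
        lr = logrank_test(t, e, x)
        assert chi2 == pytest.approx(lr.chi2, rel=1e-6)
        assert p == pytest.approx(lr.p, rel=1e-6)


class TestAssociationStats:
    def test_pearson_exact_linear(self):
        x = np.arange(10, dtype=float)
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == 0.0

    def test_pearson_null(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        r, p = pearson_corr(x, y)
        assert abs(r) < 0.05

    def test_pearson_matches_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        r, p = pearson_corr(x, y)
        ref = scipy_stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_pearson_recovers_generator_rho(self):
        rng = np.random.default_rng(10)
        n, rho = 1097, 0.891
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        r, _ = pearson_corr(z[:, 0], z[:, 1])
        se = (1 - rho**2) / np.sqrt(n - 1)
        assert abs(r - rho) < 3 * se

    def test_pearson_zero_variance(self):
        with pytest.raises(SurvivalError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_kruskal_identical_groups(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)
        assert df == 1

    def test_kruskal_brute_force_oracle(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        h, df, p = kruskal_wallis(groups)
        # brute-force ranks: values are distinct, ranks 1..9
        n = 9
        rank_sums = [6, 15, 24]
        expected = 12 / (n * (n + 1)) * sum(
            rs**2 / 3 for rs in rank_sums) - 3 * (n + 1)
        assert h == pytest.approx(expected, rel=1e-12)
        assert df == 2

    def test_kruskal_matches_scipy_with_ties(self):
        rng = np.random.default_rng(11)
        groups = [np.round(rng.normal(loc, 1, 30), 1) for loc in (0.0, 0.3, 0.8)]
        h, df, p = kruskal_wallis(groups)
        ref = scipy_stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_kruskal_permutation_invariance(self):
        g1, g2 = [3.0, 1.0, 2.0], [5.0, 4.0, 6.0]
        h1, *_ = kruskal_wallis([g1, g2])
        h2, *_ = kruskal_wallis([g1[::-1], g2[::-1]])
        assert h1 == pytest.approx(h2)

    def test_kruskal_all_identical_values(self):
        h, df, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0


class TestTruncation:
    def test_events_beyond_horizon_become_censored(self):
        t, e = truncate_followup([50, 130, 200], [1, 1, 0], 120.0)
        assert t.tolist() == [50, 120, 120]
        assert e.tolist() == [1, 0, 0]

    def test_never_increases_events(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(100, 200)
        e = (rng.random(200) < 0.7).astype(int)
        for horizon in (30, 60, 120, 1000):
            _, e2 = truncate_followup(t, e, horizon)
            assert e2.sum() <= e.sum()


class TestTable1Report:
    def test_null_cohort_mostly_ns(self):
        expr, clin, _ = simulate_cohort(CohortSimConfig(n=250, hr_signature=1.0, seed=13))
        report, meta = table1_report(expr, clin)
        cells = report[report["skipped_reason"] == ""]
        assert (cells["significant"].sum() / len(cells)) < 0.35

    def test_luminal_signature_effect_detected(self):
        cfg = CohortSimConfig(n=600, hr_signature=5.0, subtype_probs=(1.0, 0.0, 0.0),
                              seed=14)
        expr, clin, _ = simulate_cohort(cfg)
        report, _ = table1_report(expr, clin)
        cell = report[(report.marker == "signature") & (report.subclass == "Luminal")]
        assert bool(cell["significant"].iloc[0])
        assert cell["hr"].iloc[0] > 2.0

    def test_single_subtype_cohort_skips_other_strata(self):
        cfg = CohortSimConfig(n=100, subtype_probs=(1.0, 0.0, 0.0), seed=15)
        expr, clin, _ = simulate_cohort(cfg)
        report, _ = table1_report(expr, clin)
        tn = report[report.subclass == "TripleNegative"]
        assert (tn["skipped_reason"] != "").all()

    def test_na_cell_when_low_group_has_no_events(self):
        n = 40
        rng = np.random.default_rng(16)
        expr = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "wt_expr": np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 20)]),
            "de4_expr": np.concatenate([rng.uniform(0, 1, 20), rng.uniform(2, 3, 20)]),
        })
        clin = pd.DataFrame({
            "sample_id": expr.sample_id,
            "er": "+", "pr": "+", "her2": "-",
            "rfs_time": np.concatenate([np.full(20, 119.0), rng.uniform(5, 50, 20)]),
            "event": np.concatenate([np.zeros(20, int), np.ones(20, int)]),
        })
        report, _ = table1_report(expr, clin, markers={"signature": "signature"},
                                  subclasses=[])
        cell = report.iloc[0]
        assert cell["hr"] is None or (isinstance(cell["hr"], float) and np.isnan(cell["hr"]))
        assert "monotone" in cell["na_reason"]

    def test_empty_join_rejected(self):
        expr = pd.DataFrame({"sample_id": ["a"], "wt_expr": [1.0], "de4_expr": [1.0]})
        clin = pd.DataFrame({"sample_id": ["b"], "er": ["+"], "pr": ["+"],
                             "her2": ["-"], "rfs_time": [10.0], "event": [1]})
        with pytest.raises(SurvivalError):
            table1_report(expr, clin)


def test_marker_cell_skips_tiny_groups():
    cell = marker_cell("m", "all", [1, 2, 3, 4], [1, 1, 1, 0],
                       [True, False, False, False])
    assert cell.skipped_reason != ""
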