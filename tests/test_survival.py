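import math

import numpy as np
import pandas as pd
import pytest

from subtype_suite.survival import cox_fit, km_estimate, logrank
from subtype_suite.synthetic import make_clinical


def breslow_loglik(beta, times, events, x):
    """Literal Breslow partial log-likelihood (independent of the fitter)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def efron_loglik(beta, times, events, x):
    """Literal Efron partial log-likelihood for tied event times."""
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        dead = [j for j in range(len(times)) if times[j] == t and events[j] == 1]
        risk = [j for j in range(len(times)) if times[j] >= t]
        sum_risk = sum(math.exp(beta * x[j]) for j in risk)
        sum_dead = sum(math.exp(beta * x[j]) for j in dead)
        d = len(dead)
        ll += sum(beta * x[j] for j in dead)
        for m in range(d):
            ll -= math.log(sum_risk - (m / d) * sum_dead)
    return ll


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.table["survival"],
                                   [2 / 3, 1 / 3, 0.0], atol=1e-12)
        assert curve.median == 2.0

    def test_all_censored(self):
        curve = km_estimate([5, 6, 7], [0, 0, 0])
        assert (curve.table["survival"] == 1.0).all()
        assert not curve.median_reached

    def test_censoring_at_event_time_ordered_after_event(self):
        # at t=2 one event and one censoring: both count as at risk there
        curve = km_estimate([1, 2, 2, 3], [1, 1, 0, 1])
        t2 = curve.table[curve.table["time"] == 2].iloc[0]
        assert t2["at_risk"] == 3
        assert t2["survival"] == pytest.approx((3 / 4) * (2 / 3))
        t3 = curve.table[curve.table["time"] == 3].iloc[0]
        assert t3["at_risk"] == 1
        assert t3["survival"] == pytest.approx(0.0)

    def test_km_equals_empirical_fraction_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(size=50)
        curve = km_estimate(t, np.ones(50))
        last = curve.table["survival"].iloc[-1]
        assert last == pytest.approx(0.0, abs=1e-12)
        mid_time = np.median(t)
        assert curve.survival_at(mid_time) == pytest.approx(
            np.mean(t > mid_time), abs=0.03)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_lifelines_cross_check(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(1)
        t = rng.exponential(size=40)
        e = rng.integers(0, 2, size=40)
        if e.sum() == 0:
            e[0] = 1
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for _, row in curve.table.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["time"])), abs=1e-9)


class TestLogrank:
    def test_identical_groups(self):
        g = ([1, 2, 3], [1, 1, 1])
        res = logrank([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_fixture(self):
        res = logrank([([1, 2], [1, 1]), ([3, 4], [1, 1])])
        assert res.statistic == pytest.approx(2.882, abs=1e-3)
        assert res.p_value == pytest.approx(0.0896, abs=1e-3)
        assert res.extras["observed"][0] == pytest.approx(2.0)
        assert res.extras["expected"][0] == pytest.approx(0.8333, abs=1e-4)

    def test_group_relabeling_invariance(self):
        a = ([1, 4, 6], [1, 0, 1])
        b = ([2, 3, 9], [1, 1, 0])
        assert logrank([a, b]).p_value == pytest.approx(logrank([b, a]).p_value)

    def test_invariance_under_monotone_time_transform(self):
        rng = np.random.default_rng(2)
        a = (rng.exponential(size=20), rng.integers(0, 2, size=20))
        b = (rng.exponential(2.0, size=20), rng.integers(0, 2, size=20))
        p1 = logrank([a, b]).p_value
        p2 = logrank([(np.exp(a[0]), a[1]), (np.exp(b[0]), b[1])]).p_value
        assert p1 == pytest.approx(p2)

    def test_three_groups_against_lifelines(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(3)
        times = rng.exponential(size=60)
        events = rng.integers(0, 2, size=60)
        groups = np.repeat([0, 1, 2], 20)
        mine = logrank([(times[groups == g], events[groups == g])
                        for g in range(3)])
        ref = multivariate_logrank_test(times, groups, events)
        assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-6)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank([([1, 2], [0, 0]), ([3], [0])])


class TestCox:
    def test_identical_event_patterns_give_null_effect(self):
        times = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.repeat([0.0, 1.0], 4)
        fit = cox_fit(times, events, x)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_grid_search_partial_likelihood(self, ties):
        times = np.array([3.0, 5.0, 7.0, 2.0, 10.0, 4.0, 6.0, 1.0])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0])
        fit = cox_fit(times, events, x, ties=ties)
        oracle = breslow_loglik if ties == "breslow" else efron_loglik
        grid = np.arange(-3, 3, 1e-4)
        lls = [oracle(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert fit.beta[0] == pytest.approx(beta_star, abs=1e-4)
        assert fit.loglik == pytest.approx(max(lls), abs=1e-6)

    def test_efron_with_ties_matches_grid_search(self):
        times = np.array([2.0, 2.0, 2.0, 5.0, 5.0, 8.0, 9.0, 9.0])
        events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
        fit = cox_fit(times, events, x, ties="efron")
        grid = np.arange(-3, 3, 1e-4)
        lls = [efron_loglik(b, times, events, x) for b in grid]
        assert fit.beta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_lifelines_cross_check_efron(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        fit = cox_fit(t, e, x)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        assert fit.beta[0] == pytest.approx(ref.params_["x"], abs=1e-6)
        assert fit.se[0] == pytest.approx(ref.standard_errors_["x"], abs=1e-6)

    def test_multivariable_lifelines_cross_check(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(5)
        n = 150
        X = pd.DataFrame({"a": rng.normal(size=n),
                          "b": rng.integers(0, 2, size=n).astype(float)})
        t = rng.exponential(1 / np.exp(0.4 * X["a"] - 0.6 * X["b"]))
        e = (rng.uniform(size=n) < 0.7).astype(int)
        fit = cox_fit(t, e, X)
        df = X.assign(t=t, e=e)
        ref = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        np.testing.assert_allclose(fit.beta, ref.params_[["a", "b"]], atol=1e-6)

    def test_complete_separation_flagged(self):
        times = np.array([1, 2, 3, 4, 10, 11, 12, 13], dtype=float)
        events = np.ones(8, dtype=int)
        x = np.repeat([1.0, 0.0], 4)  # all early events in one group
        fit = cox_fit(times, events, x)
        assert not fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit([1, 2, 3], [1, 1, 0], [1.0, 1.0, 1.0])

    def test_loglik_at_estimate_dominates_null(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=60)
        t = rng.exponential(1 / np.exp(0.3 * x))
        fit = cox_fit(t, np.ones(60), x)
        assert fit.loglik >= fit.loglik_null - 1e-9

    def test_ci_contains_hr(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        t = rng.exponential(size=50)
        fit = cox_fit(t, np.ones(50), x)
        assert fit.ci_lower[0] <= fit.hr[0] <= fit.ci_upper[0]


class TestPlantedSurvival:
    def test_arm_effect_recovered(self):
        labels = np.ones(2000, dtype=int)
        clin, _ = make_clinical(labels, {1: 0.05}, arm_effect=0.5,
                                censor_rate=0.2, seed=8)
        df = clin.data
        fit = cox_fit(df["pfs_time"], df["pfs_event"], df[["arm"]].astype(float))
        assert 0.45 < fit.hr[0] < 0.56

    def test_null_logrank_uniform(self):
        """Equal hazards in both clusters: ~5% rejections across seeds."""
        rejections = 0
        n_rep = 300
        for seed in range(n_rep):
            labels = np.repeat([1, 2], 25)
            clin, _ = make_clinical(labels, {1: 0.05, 2: 0.05},
                                    censor_rate=0.2, seed=seed)
            df = clin.data
            groups = [(df.loc[df["cluster"] == c, "pfs_time"],
                       df.loc[df["cluster"] == c, "pfs_event"]) for c in (1, 2)]
            rejections += logrank(groups).p_value < 0.05
        from scipy.stats import binom
        lo, hi = binom.interval(0.999, n_rep, 0.05)
        assert lo <= rejections <= hi
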