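import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirdupscreen.survival_stats import (
    CoxResult,
    cox_fit,
    cox_score_at_zero,
    forest_summary,
    km_estimate,
    logrank_test,
    median_split,
    spearman,
    truncate_follow_up,
)


def naive_product_limit(times, events, t):
    """O(n^2) product-limit oracle: explicit product over event times <= t."""
    s = 1.0
    for u in sorted(set(tt for tt, ee in zip(times, events) if ee == 1)):
        if u > t:
            break
        n_at_risk = sum(1 for tt in times if tt >= u)
        d = sum(1 for tt, ee in zip(times, events) if tt == u and ee == 1)
        s *= 1 - d / n_at_risk
    return s


def logrank_oe(times_a, events_a, times_b, events_b):
    """Observed-minus-expected events in group A (independent tally)."""
    t = list(times_a) + list(times_b)
    e = list(events_a) + list(events_b)
    a = [True] * len(times_a) + [False] * len(times_b)
    oe = 0.0
    for u in sorted(set(tt for tt, ee in zip(t, e) if ee == 1)):
        n = sum(1 for tt in t if tt >= u)
        n1 = sum(1 for tt, aa in zip(t, a) if tt >= u and aa)
        d = sum(1 for tt, ee in zip(t, e) if tt == u and ee == 1)
        d1 = sum(1 for tt, ee, aa in zip(t, e, a) if tt == u and ee == 1 and aa)
        oe += d1 - d * n1 / n
    return oe


def _censored_sample(rng, n, scale=10.0, censor=0.3):
    t_event = rng.exponential(scale, size=n)
    t_cens = rng.exponential(scale / censor, size=n)
    times = np.round(np.minimum(t_event, t_cens), 1) + 0.1  # rounding forces ties
    events = (t_event <= t_cens).astype(int)
    return times, events


class TestMedianSplit:
    def test_even_split_without_ties(self):
        labels = median_split([1, 2, 3, 4])
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_ties_at_median_go_low(self):
        labels = median_split([1, 2, 2, 3])
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_continuous_values_split_near_half(self):
        rng = np.random.default_rng(0)
        labels = median_split(rng.normal(size=500))
        diff = abs((labels == "low").sum() - (labels == "high").sum())
        assert diff in (0, 1)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            median_split([5, 5, 5])


class TestTruncateFollowUp:
    def test_events_beyond_horizon_recoded_censored(self):
        t, e = truncate_follow_up([10, 70, 80], [1, 1, 0], horizon=60)
        assert t.tolist() == [10, 60, 60]
        assert e.tolist() == [1, 0, 0]


class TestKaplanMeier:
    def test_no_events_gives_unit_survival(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.survival_at(100) == 1.0

    def test_all_events_hand_computed(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])

    def test_matches_naive_product_limit(self):
        rng = np.random.default_rng(4)
        times, events = _censored_sample(rng, 80)
        curve = km_estimate(times, events)
        for u, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(naive_product_limit(times, events, u), abs=0)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        times, events = _censored_sample(rng, 120)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for u, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(kmf.predict(u), abs=1e-12)

    def test_non_increasing_and_bounded(self):
        rng = np.random.default_rng(6)
        times, events = _censored_sample(rng, 60)
        curve = km_estimate(times, events)
        assert (np.diff(curve.survival) <= 1e-15).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()

    def test_no_censoring_ends_at_zero(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(5, size=30)
        curve = km_estimate(t, np.ones(30, int))
        assert curve.survival[-1] == pytest.approx(0.0, abs=0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 0]
        chi2, p = logrank_test((t, e), (t, e))
        assert chi2 == 0.0
        assert p == 1.0

    def test_single_event_time_closed_form(self):
        # A: one event at t=5 among 10 at risk; B: 10 at risk, no events.
        ta = [5.0] + [9.0] * 9
        ea = [1] + [0] * 9
        tb = [9.0] * 10
        eb = [0] * 10
        chi2, p = logrank_test((ta, ea), (tb, eb))
        # closed form: O-E = 1 - 10/20 = 0.5; V = 1*(1/2)(1/2)(19/19) = 0.25
        assert chi2 == pytest.approx(0.5**2 / 0.25, abs=0)
        assert p == pytest.approx(float(sps.chi2.sf(1.0, 1)), abs=0)

    def test_zero_events_reported_as_null(self):
        chi2, p = logrank_test(([1, 2], [0, 0]), ([3, 4], [0, 0]))
        assert (chi2, p) == (0.0, 1.0)

    def test_group_relabeling_invariance(self):
        rng = np.random.default_rng(10)
        ga = _censored_sample(rng, 40)
        gb = _censored_sample(rng, 55)
        assert logrank_test(ga, gb) == logrank_test(gb, ga)

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(12)
        ta, ea = _censored_sample(rng, 70)
        tb, eb = _censored_sample(rng, 90, scale=6.0)
        chi2, p = logrank_test((ta, ea), (tb, eb))
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-10)
        assert p == pytest.approx(ref.p_value, rel=1e-10)


class TestCox:
    def test_score_at_zero_equals_logrank_oe(self):
        rng = np.random.default_rng(14)
        n = 60
        x = rng.integers(0, 2, size=n).astype(float)
        times = rng.exponential(10.0 / np.exp(0.5 * x))  # continuous: no ties
        events = (rng.uniform(size=n) < 0.8).astype(int)
        oe = logrank_oe(times[x == 1], events[x == 1], times[x == 0], events[x == 0])
        assert cox_score_at_zero(times, events, x) == pytest.approx(oe, rel=1e-12)

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(15)
        n = 250
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        x3 = rng.integers(1, 5, n).astype(float)
        tt = np.round(rng.exponential(1 / np.exp(0.6 * x1 + 0.2 * x2)), 1) + 0.1
        ev = (rng.uniform(size=n) < 0.7).astype(int)
        df = pd.DataFrame({"time": tt, "event": ev, "x1": x1, "x2": x2, "x3": x3})
        res = cox_fit(df, ["x1", "x2", "x3"])
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        np.testing.assert_allclose(res.log_hr, cph.params_.values, atol=1e-6)
        np.testing.assert_allclose(res.se, cph.standard_errors_.values, atol=1e-6)
        assert res.converged

    def test_parameter_recovery_and_coverage(self):
        rng = np.random.default_rng(16)
        estimates, covered = [], 0
        n_rep = 50
        for _ in range(n_rep):
            n = 500
            x = rng.integers(0, 2, n).astype(float)
            t_event = rng.exponential(1.0 / (0.05 * 2.0**x))
            t_cens = rng.uniform(0, 40, size=n)  # ~30% censoring
            tt = np.minimum(t_event, t_cens)
            ev = (t_event <= t_cens).astype(int)
            df = pd.DataFrame({"time": tt, "event": ev, "x": x})
            res = cox_fit(df, ["x"])
            estimates.append(res.log_hr[0])
            lo, hi = res.ci95_low[0], res.ci95_high[0]
            covered += lo <= 2.0 <= hi
        mean_hr = float(np.exp(np.mean(estimates)))
        assert 1.8 <= mean_hr <= 2.2
        assert covered >= 0.86 * n_rep

    def test_constant_covariate_named(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [1, 1], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            cox_fit(df, ["flat"])

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=30)
        df = pd.DataFrame(
            {"time": rng.exponential(5, 30), "event": np.ones(30, int), "a": x, "b": 2 * x}
        )
        with pytest.raises(ValueError, match="rank"):
            cox_fit(df, ["a", "b"])

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="event"):
            cox_fit(df, ["x"])

    def test_affine_rescaling_of_covariate(self):
        rng = np.random.default_rng(18)
        n = 150
        x = rng.normal(size=n)
        tt = rng.exponential(1 / np.exp(0.4 * x))
        ev = (rng.uniform(size=n) < 0.8).astype(int)
        df = pd.DataFrame({"time": tt, "event": ev, "x": x, "x10": 10 * x + 3})
        r1 = cox_fit(df, ["x"])
        r2 = cox_fit(df, ["x10"])
        assert r2.log_hr[0] * 10 == pytest.approx(r1.log_hr[0], rel=1e-6)
        assert r2.p[0] == pytest.approx(r1.p[0], rel=1e-6)


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, x)[0] == 1.0
        assert spearman(x, [-v**3 for v in x])[0] == -1.0

    def test_matches_midrank_pearson_oracle_with_ties(self):
        rng = np.random.default_rng(20)
        x = rng.integers(0, 20, size=200).astype(float)  # heavy ties
        y = -x + rng.integers(0, 10, size=200)
        rho, p = spearman(x, y)
        ref_rho, ref_p = sps.spearmanr(x, y)
        assert rho == pytest.approx(ref_rho, abs=1e-12)
        assert p == pytest.approx(ref_p, rel=1e-9)

    def test_sign_flip_under_decreasing_transform(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        rho, _ = spearman(x, y)
        rho_flipped, _ = spearman(x, -y)
        assert rho_flipped == pytest.approx(-rho, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="3"):
            spearman([1, 2], [3, 4])


class TestForestSummary:
    def _result(self, log_hr, se):
        return CoxResult(
            covariates=["expression_low", "stage"],
            log_hr=np.array([log_hr, 0.1]),
            se=np.array([se, 0.2]),
            n=100,
            n_events=50,
            converged=True,
            iterations=5,
        )

    def test_empty_input(self):
        assert forest_summary({}).empty

    def test_ordered_by_p(self):
        results = {
            "weak": self._result(0.3, 0.25),
            "strong": self._result(0.9, 0.2),
        }
        table = forest_summary(results)
        assert table["gene"].tolist() == ["strong", "weak"]
        assert (table["p"].diff().dropna() >= 0).all()

    def test_round_trips_through_write_results(self, tmp_path):
        from mirdupscreen.io_formats import read_result_table, write_results

        table = forest_summary({"g1": self._result(0.5, 0.1)})
        write_results({"cox_forest": table}, tmp_path)
        back = read_result_table(tmp_path / "cox_forest.tsv")
        np.testing.assert_allclose(back["hr"], table["hr"], rtol=1e-9)
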