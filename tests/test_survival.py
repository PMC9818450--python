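"""Survival machinery: KM, log-rank, Cox partial likelihood, time-dependent ROC.

Independent oracles: hand product-limit arithmetic, brute-force grid
maximization of the explicit partial likelihood, pairwise Mann-Whitney
concordance counts, and lifelines as an external cross-check.
"""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from survscreen import (
    NOT_REACHED,
    SurvivalError,
    auc_trajectory,
    cox_fit,
    cox_score_test,
    km_estimate,
    logrank_test,
    td_roc,
)


def explicit_partial_loglik(beta, x, times, events):
    """Textbook no-ties Cox partial likelihood, evaluated literally."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def grid_max_beta(x, times, events, lo=-5.0, hi=5.0, step=1e-4):
    grid = np.arange(lo, hi + step, step)
    vals = [explicit_partial_loglik(b, x, times, events) for b in grid]
    return grid[int(np.argmax(vals))]


class TestKaplanMeier:
    def test_hand_computed_curve(self):
        km = km_estimate([1, 2, 3], [1, 0, 1])
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        np.testing.assert_array_equal(km.event_times, [1, 3])
        assert km.median == 3

    def test_all_censored_flat_curve(self):
        km = km_estimate([5, 8, 13], [0, 0, 0])
        assert km.event_times.size == 0
        assert km.median == NOT_REACHED
        assert km.survival_at(10.0) == 1.0

    def test_single_subject_event(self):
        km = km_estimate([5], [1])
        np.testing.assert_allclose(km.survival, [0.0])
        assert km.median == 5

    def test_censored_only_times_do_not_change_survival(self):
        base = km_estimate([1, 2, 4], [1, 1, 1])
        extra = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        # the censored subject at t=3 shrinks the risk set at t=4 but adds no step
        np.testing.assert_array_equal(base.event_times, extra.event_times)
        assert extra.survival[-1] == 0.0

    @given(st.lists(st.integers(1, 60), min_size=1, max_size=40))
    def test_no_censoring_matches_empirical_cdf(self, raw_times):
        """With every subject an event, KM is 1 - ECDF at each event time."""
        times = np.array(raw_times, dtype=float)
        km = km_estimate(times, np.ones_like(times, dtype=int))
        for t, s in zip(km.event_times, km.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_matches_lifelines(self, no_tie_survival):
        lifelines = pytest.importorskip("lifelines")
        _, times, events = no_tie_survival
        km = km_estimate(times, events)
        kmf = lifelines.KaplanMeierFitter().fit(times, events)
        theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
        np.testing.assert_allclose(km.survival, theirs, atol=1e-10)


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [1, 3, 5, 1, 3, 5]
        e = [1, 0, 1, 1, 0, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_group(self):
        """Group A events at 1 and 2, group B censored at 10 twice.

        t=1: n=4, nA=2, d=1 -> E_A = 1/2, V = (2*2*1*3)/(16*3) = 1/4
        t=2: n=3, nA=1, d=1 -> E_A = 1/3, V = (1*2*1*2)/(9*2)  = 2/9
        O-E = 2 - 5/6 = 7/6; chi2 = (7/6)^2 / (1/4 + 2/9)
        """
        t = [1, 2, 10, 10]
        e = [1, 1, 0, 0]
        g = ["A", "A", "B", "B"]
        expected = (7 / 6) ** 2 / (1 / 4 + 2 / 9)
        res = logrank_test(t, e, g)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.dof == 1

    def test_relabeling_invariance(self, no_tie_survival):
        _, times, events = no_tie_survival
        g = (np.arange(times.size) % 2).astype(int)
        a = logrank_test(times, events, g)
        b = logrank_test(times, events, 1 - g)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_three_group_dof_and_lifelines_agreement(self, no_tie_survival):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import multivariate_logrank_test

        _, times, events = no_tie_survival
        g = np.arange(times.size) % 3
        res = logrank_test(times, events, g)
        theirs = multivariate_logrank_test(times, g, events)
        assert res.dof == 2
        assert res.statistic == pytest.approx(theirs.test_statistic, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(SurvivalError):
            logrank_test([1, 2, 3], [1, 1, 1], [0, 0, 0])


class TestCox:
    def test_identical_event_patterns_give_beta_zero(self):
        # both groups see exactly the same times and events -> HR = 1
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.array([1, 0, 1, 1, 0, 1])
        x = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        fit = cox_fit(x[:, None], t, e)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(0.0, abs=1e-7)
        assert fit.hazard_ratios[0] == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_grid_oracle_on_tiny_fixtures(self, seed):
        """NR estimate equals brute-force maximization of the literal
        partial likelihood on <=12-subject no-tie fixtures, to 1e-4."""
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 13)
        times = rng.permutation(np.arange(1, n + 1)).astype(float)
        events = rng.integers(0, 2, n)
        events[rng.integers(n)] = 1  # at least one event
        x = rng.integers(0, 2, n).astype(float)
        if x.std() == 0:
            x[0] = 1 - x[0]
        fit = cox_fit(x[:, None], times, events)
        if not fit.converged:  # separated fixture: oracle hits the grid edge
            assert abs(grid_max_beta(x, times, events)) > 4.9
            return
        assert fit.coef[0] == pytest.approx(grid_max_beta(x, times, events), abs=1e-4)

    def test_separation_flagged_not_silent(self):
        # all high-group events precede every low-group event
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        fit = cox_fit(x[:, None], t, e)
        assert not fit.converged

    def test_constant_covariate_rejected(self):
        with pytest.raises(SurvivalError, match="constant"):
            cox_fit(np.ones((5, 1)), [1, 2, 3, 4, 5], [1, 1, 0, 1, 1])

    def test_no_events_rejected(self):
        with pytest.raises(SurvivalError):
            cox_fit(np.array([[1.0], [0.0]]), [1, 2], [0, 0])

    def test_sign_agrees_with_km_ordering(self, small_cohort):
        """For a binary covariate, beta > 0 iff the high group's KM curve
        lies below (worse survival)."""
        cohort, _ = small_cohort
        marker = cohort.expression.gene("G0000")
        times, events = cohort.clinical.survival("OS")
        hi = marker > np.median(marker)
        fit = cox_fit(hi.astype(float)[:, None], times, events)
        km_hi = km_estimate(times[hi], events[hi])
        km_lo = km_estimate(times[~hi], events[~hi])
        t_grid = np.quantile(times, [0.3, 0.5, 0.7])
        below = np.mean(km_hi.survival_at(t_grid) < km_lo.survival_at(t_grid))
        assert (fit.coef[0] > 0) == (below > 0.5)

    def test_multivariate_matches_lifelines(self, no_tie_survival):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        x, times, events = no_tie_survival
        rng = np.random.default_rng(9)
        X = np.column_stack([x, rng.normal(size=x.size), rng.integers(0, 2, x.size)])
        fit = cox_fit(X, times, events)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = times, events
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(fit.coef, cph.params_.to_numpy(), atol=2e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.to_numpy(), atol=2e-5)

    def test_efron_ties_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        rng = np.random.default_rng(4)
        n = 60
        x = rng.normal(size=n)
        times = np.ceil(10 * (-np.log(rng.random(n)) / np.exp(0.5 * x)))  # heavy ties
        events = rng.integers(0, 2, n)
        events[:5] = 1
        fit = cox_fit(x[:, None], times, events, tie_method="efron")
        df = pd.DataFrame({"x": x, "T": times, "E": events})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert fit.coef[0] == pytest.approx(cph.params_.iloc[0], abs=2e-5)

    def test_logrank_equals_squared_cox_score(self, no_tie_survival):
        """Classical identity on no-tie data: the two-group log-rank
        chi-square equals the Cox score test of the group indicator."""
        _, times, events = no_tie_survival
        g = (np.arange(times.size) % 2).astype(float)
        lr = logrank_test(times, events, g.astype(int))
        score, _ = cox_score_test(g[:, None], times, events)
        assert lr.statistic == pytest.approx(score, abs=1e-6)


class TestTdROC:
    def test_perfect_marker_auc_one(self):
        times = np.array([1.0, 2.0, 3.0, 40.0, 50.0, 60.0])
        events = np.ones(6, dtype=int)
        marker = np.array([10.0, 9.0, 8.0, 1.0, 2.0, 3.0])
        roc = td_roc(marker, times, events, horizon=10.0)
        assert roc.auc == pytest.approx(1.0)
        both = (roc.sensitivity == 1.0) & (roc.specificity == 1.0)
        assert both.any()

    @pytest.mark.parametrize("seed", range(5))
    def test_uncensored_limit_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        marker = rng.normal(size=n)
        times = rng.exponential(20, n) + 0.5
        events = np.ones(n, dtype=int)
        h = float(np.quantile(times, 0.5))
        roc = td_roc(marker, times, events, h)
        died = times <= h
        u = mannwhitneyu(marker[died], marker[~died]).statistic
        assert roc.auc == pytest.approx(u / (died.sum() * (~died).sum()), abs=1e-12)

    def test_monotone_transform_invariance(self, no_tie_survival):
        x, times, events = no_tie_survival
        a = td_roc(x, times, events, 15.0)
        b = td_roc(np.exp(x), times, events, 15.0)
        assert a.auc == pytest.approx(b.auc, abs=1e-12)

    def test_no_cases_rejected(self):
        with pytest.raises(SurvivalError, match="no cases"):
            td_roc([1.0, 2.0], [50.0, 60.0], [1, 1], horizon=10.0)

    def test_null_marker_auc_centered_at_half(self):
        """Marker independent of survival: mean AUC ~ 0.5 over replicates."""
        rng = np.random.default_rng(12)
        aucs = []
        for _ in range(200):
            n = 500
            marker = rng.normal(size=n)
            t_event = rng.exponential(30, n)
            c = rng.uniform(0, 80, n)
            times = np.minimum(t_event, c) + 1e-9
            events = (t_event <= c).astype(int)
            aucs.append(td_roc(marker, times, events, 24.0).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03


class TestAucTrajectory:
    def test_single_horizon_consistent_with_td_roc(self, no_tie_survival):
        x, times, events = no_tie_survival
        series = auc_trajectory(x, times, events, [15.0])
        assert len(series) == 1
        assert series[0][1] == pytest.approx(td_roc(x, times, events, 15.0).auc)

    def test_prognostic_marker_aucs_above_half(self, small_cohort):
        cohort, _ = small_cohort
        times, events = cohort.clinical.survival("OS")
        marker = cohort.expression.gene("G0000")
        series = auc_trajectory(marker, times, events, [12.0, 24.0, 36.0])
        assert all(auc > 0.5 for _, auc in series)

    def test_invalid_horizon_skipped_with_warning(self, no_tie_survival):
        x, times, events = no_tie_survival
        with pytest.warns(UserWarning, match="skipped"):
            series = auc_trajectory(x, times, events, [15.0, 1e6])
        assert len(series) == 1
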