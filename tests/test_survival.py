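"""Kaplan–Meier, Yates log-rank and Newton–Raphson Cox primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survscan.survival import (cox_fit, cox_score_statistic, km_estimate,
                               logrank_yates)

from oracles import brute_force_logrank, grid_search_cox


class TestKaplanMeier:
    @pytest.mark.parametrize("times,events,expected", [
        ([1, 2, 3], [0, 0, 0], [1.0, 1.0, 1.0]),
        ([1, 2, 3, 4], [1, 1, 0, 1], [0.75, 0.50, 0.50, 0.0]),
        ([5], [1], [0.0]),
    ])
    def test_hand_examples(self, times, events, expected):
        km = km_estimate(times, events)
        np.testing.assert_allclose(km.survival, expected)

    def test_matches_empirical_survivor_without_censoring(self, rng):
        t = rng.exponential(10, size=80).round(1)
        km = km_estimate(t, np.ones(80))
        for ti, s in zip(km.times, km.survival):
            np.testing.assert_allclose(s, (t > ti).mean(), atol=1e-12)

    @given(st.lists(st.tuples(st.floats(0.0, 100.0), st.integers(0, 1)),
                    min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_bounded(self, data):
        times = [d[0] for d in data]
        events = [d[1] for d in data]
        km = km_estimate(times, events)
        assert np.all(km.survival <= 1.0 + 1e-12)
        assert np.all(km.survival >= -1e-12)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(np.diff(km.n_risk) < 0)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            km_estimate([], [])
        with pytest.raises(ValueError):
            km_estimate([-1.0], [1])


class TestLogRankYates:
    def test_identical_groups_give_null(self):
        t = [2.0, 5.0, 7.0, 2.0, 5.0, 7.0]
        e = [1, 0, 1, 1, 0, 1]
        r = logrank_yates(t, e, ["A"] * 3 + ["B"] * 3)
        assert r.score == pytest.approx(0.0, abs=1e-12)
        assert r.chi2 == 0.0
        assert r.p == 1.0

    def test_matches_brute_force_hypergeometric(self):
        # separated groups: A dies at 1,2,3; B at 4,5,6 (no censoring)
        t = [1, 2, 3, 4, 5, 6]
        e = [1] * 6
        g = ["A"] * 3 + ["B"] * 3
        r = logrank_yates(t, e, g)
        O1, E1, V = brute_force_logrank(t, e, np.array(g) == "A")
        assert r.observed[0] == pytest.approx(O1)
        assert r.expected[0] == pytest.approx(E1)
        assert r.variance == pytest.approx(V)
        corrected = max(0.0, abs(O1 - E1) - 0.5)
        assert r.chi2 == pytest.approx(corrected**2 / V)

    def test_matches_brute_force_with_censoring(self, rng, small_survival):
        times, events = small_survival
        g = rng.integers(0, 2, size=times.size)
        r = logrank_yates(times, events, g)
        O1, E1, V = brute_force_logrank(times, events, g == 0)
        assert r.observed[0] == pytest.approx(O1)
        assert r.expected[0] == pytest.approx(E1)
        assert r.variance == pytest.approx(V)

    def test_label_swap_symmetric(self, rng, small_survival):
        times, events = small_survival
        g = rng.integers(0, 2, size=times.size)
        a = logrank_yates(times, events, g)
        b = logrank_yates(times, events, 1 - g)
        assert a.chi2 == pytest.approx(b.chi2, abs=1e-12)
        assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_permutation_type_one_error_is_conservative(self, rng, small_survival):
        """Yates' correction keeps the null rejection rate at or below nominal."""
        times, events = small_survival
        g0 = np.repeat([0, 1], times.size // 2)
        n_perm = 2000
        rej = sum(logrank_yates(times, events, rng.permutation(g0)).p < 0.05
                  for _ in range(n_perm))
        se = np.sqrt(0.05 * 0.95 / n_perm)
        assert rej / n_perm <= 0.05 + 2 * se

    def test_requires_two_nonempty_groups_and_an_event(self):
        with pytest.raises(ValueError):
            logrank_yates([1, 2], [1, 1], ["A", "A"])
        with pytest.raises(ValueError):
            logrank_yates([1, 2], [0, 0], ["A", "B"])


class TestCoxFit:
    def test_symmetric_groups_give_null_hr(self):
        t = np.tile([3.0, 6.0, 9.0, 12.0], 2)
        e = np.tile([1, 1, 0, 1], 2)
        x = np.repeat([0.0, 1.0], 4)
        fit = cox_fit(t, e, x.reshape(-1, 1))
        assert abs(fit.coef[0]) < 1e-6
        assert fit.hr[0] == pytest.approx(1.0, abs=1e-5)

    def test_matches_grid_search_oracle_interior(self):
        # interleaved covariate => interior maximiser of the partial likelihood
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 1, 1]
        x = [1.0, 0.0, 1.0, 0.0]
        fit = cox_fit(t, e, np.array(x).reshape(-1, 1))
        beta_star = grid_search_cox(t, e, x)
        assert fit.converged
        assert fit.coef[0] == pytest.approx(beta_star, abs=1e-4)

    def test_matches_grid_search_oracle_eight_patients(self, rng):
        t = rng.exponential(10, size=8).round(2) + 0.5
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        x = rng.normal(size=8).round(2)
        fit = cox_fit(t, e, x.reshape(-1, 1))
        beta_star = grid_search_cox(t, e, x)
        assert fit.coef[0] == pytest.approx(beta_star, abs=1e-4)

    def test_monotone_likelihood_flagged(self):
        # both x=1 patients die first: likelihood increases without bound
        fit = cox_fit([1, 2, 3, 4], [1, 1, 1, 1],
                      np.array([1.0, 1.0, 0.0, 0.0]).reshape(-1, 1))
        assert not fit.converged
        assert "monotone" in fit.message

    def test_agrees_with_lifelines(self, rng):
        """Efron fits match an established implementation to 1e-4 in beta."""
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd
        for _ in range(20):
            n = 70
            X = rng.normal(size=(n, 2))
            lam = 0.05 * np.exp(X @ [0.6, -0.4])
            te = rng.exponential(1 / lam)
            tc = rng.exponential(25, size=n)
            times = np.round(np.minimum(te, tc), 1) + 0.1
            events = (te <= tc).astype(int)
            if events.sum() < 5:
                continue
            fit = cox_fit(times, events, X, ties="efron")
            df = pd.DataFrame(X, columns=["a", "b"])
            df["T"], df["E"] = times, events
            cph = lifelines.CoxPHFitter().fit(df, "T", "E")
            np.testing.assert_allclose(fit.coef, cph.params_.values, atol=1e-4)
            np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-4)

    def test_score_test_equals_uncorrected_logrank(self, rng, small_survival):
        times, events = small_survival
        g = rng.integers(0, 2, size=times.size)
        r = logrank_yates(times, events, g)
        uncorrected = r.score**2 / r.variance
        assert cox_score_statistic(times, events, g) == pytest.approx(
            uncorrected, abs=1e-6)

    def test_ci_brackets_hr_and_wald_p(self, rng, small_survival):
        times, events = small_survival
        x = rng.normal(size=times.size)
        fit = cox_fit(times, events, x.reshape(-1, 1))
        assert fit.ci_lower[0] < fit.hr[0] < fit.ci_upper[0]
        assert 0 < fit.p[0] <= 1
        assert np.isfinite(fit.aic)

    def test_rejects_degenerate_designs(self, small_survival):
        times, events = small_survival
        with pytest.raises(ValueError):
            cox_fit(times, events, np.ones((times.size, 1)))
        x = np.random.default_rng(0).normal(size=times.size)
        with pytest.raises(ValueError):
            cox_fit(times, events, np.column_stack([x, 2 * x]))
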