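"""Optimal-cutoff scanning and Storey q-values."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from survscan.scan import scan_feature, scan_gene_set, scan_matrix, storey_qvalues
from survscan.survival import logrank_yates

from oracles import exhaustive_scan


@pytest.fixture
def scan_data(rng):
    n = 60
    values = rng.normal(size=n)
    te = rng.exponential(20 * np.exp(-0.5 * values))
    tc = rng.exponential(40, size=n)
    times = np.minimum(te, tc)
    events = (te <= tc).astype(int)
    return values, times, events


class TestScanFeature:
    def test_candidate_count_n10(self, rng):
        """With 10 distinct values and 10–90% bounds every split 1..9 is admissible."""
        values = np.arange(10, dtype=float)
        times = rng.exponential(10, size=10)
        res = scan_feature(values, times, np.ones(10, int))
        assert res.n_candidates == 9
        assert res.n_low + res.n_high == 10
        assert 0.10 <= res.low_fraction <= 0.90

    def test_constant_feature_not_scannable(self, small_survival):
        times, events = small_survival
        res = scan_feature(np.ones(times.size), times, events)
        assert not res.scannable
        assert np.isnan(res.p)

    def test_matches_exhaustive_split_oracle(self, scan_data):
        values, times, events = scan_data
        res = scan_feature(values, times, events)
        cut, p, n_cand = exhaustive_scan(values, times, events, logrank_yates)
        assert res.n_candidates == n_cand
        assert res.cutoff == pytest.approx(cut)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_monotone_transform_invariance(self, scan_data):
        values, times, events = scan_data
        a = scan_feature(values, times, events)
        b = scan_feature(np.exp(values), times, events)
        assert a.p == pytest.approx(b.p, rel=1e-12)
        assert a.n_low == b.n_low
        assert a.hr == pytest.approx(b.hr, rel=1e-9)
        # the cutoff maps between the midpoints of the transformed ordering
        assert np.exp(a.cutoff) == pytest.approx(b.cutoff, rel=0.2)

    def test_min_p_not_worse_than_median_split(self, scan_data):
        values, times, events = scan_data
        res = scan_feature(values, times, events)
        median_split = (values > np.median(values)).astype(int)
        assert res.p <= logrank_yates(times, events, median_split).p + 1e-15

    def test_group_sizes_respect_bounds(self, rng):
        for _ in range(5):
            n = int(rng.integers(20, 120))
            v = rng.normal(size=n)
            t = rng.exponential(15, size=n)
            e = rng.integers(0, 2, size=n)
            if e.sum() == 0:
                e[0] = 1
            res = scan_feature(v, t, e)
            assert 0.10 - 1e-9 <= res.n_low / n <= 0.90 + 1e-9

    def test_tied_values_never_split(self, small_survival):
        times, events = small_survival
        v = np.repeat([1.0, 2.0, 3.0], 20)
        res = scan_feature(v, times, events)
        # cutoff falls strictly between distinct values
        assert res.cutoff in (1.5, 2.5)


class TestScanMatrix:
    def test_gene_absent_from_matrix_logged_and_skipped(self, rng, small_survival):
        times, events = small_survival
        expr = pd.DataFrame(rng.normal(size=(3, times.size)),
                            index=["G1", "G2", "G3"],
                            columns=[f"P{i}" for i in range(times.size)])
        clinical = pd.DataFrame({
            "cohort": ["A"] * 30 + ["B"] * 30,
            "os_months": times, "event": events}, index=expr.columns)
        out = scan_gene_set(expr, clinical, ["G1", "G2", "G3", "G_MISSING"])
        assert set(out) == {"A", "B"}
        assert list(out["A"].index) == ["G1", "G2", "G3"]

    def test_qvalues_only_for_scannable(self, rng, small_survival):
        times, events = small_survival
        expr = pd.DataFrame(rng.normal(size=(4, times.size)),
                            index=list("abcd"),
                            columns=[f"P{i}" for i in range(times.size)])
        expr.loc["c"] = 1.0  # constant => not scannable
        res = scan_matrix(expr, times, events)
        assert not res.loc["c", "scannable"]
        assert np.isnan(res.loc["c", "q"])
        assert res.loc[["a", "b", "d"], "q"].notna().all()

    def test_null_scan_is_anticonservative(self, rng):
        """Min-p selection inflates the p<0.05 fraction well above nominal."""
        n, m = 80, 120
        times = rng.exponential(20, size=n)
        events = (rng.uniform(size=n) < 0.3).astype(int)
        events[0] = 1
        expr = pd.DataFrame(rng.normal(size=(m, n)),
                            index=[f"G{i}" for i in range(m)],
                            columns=[f"P{i}" for i in range(n)])
        res = scan_matrix(expr, times, events)
        assert (res["p"] < 0.05).mean() > 0.05


class TestStoreyQValues:
    def test_single_p_with_forced_pi0(self):
        q = storey_qvalues([0.5], pi0=1.0)
        assert q.qvalues[0] == pytest.approx(0.5)

    def test_step_up_minimisation_by_hand(self):
        q = storey_qvalues([0.01, 0.02, 0.03, 0.5], pi0=1.0)
        np.testing.assert_allclose(q.qvalues, [0.04, 0.04, 0.04, 0.5])

    def test_equals_bh_when_pi0_is_one(self, rng):
        p = rng.uniform(size=200)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(q.qvalues, bh, atol=1e-12)

    def test_uniform_null_pi0_near_one(self, rng):
        p = rng.uniform(size=1000)
        assert 0.85 <= storey_qvalues(p, method="smoother").pi0 <= 1.0
        assert 0.85 <= storey_qvalues(p, method="fixed").pi0 <= 1.0

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.uniform(size=50)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q.qvalues[order]) >= -1e-15)
        assert np.all((q.qvalues >= 0) & (q.qvalues <= 1))
        assert 0 < q.pi0 <= 1

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])
        with pytest.raises(ValueError):
            storey_qvalues([])
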