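"""Mobile-threshold screening, log-rank/KM statistics, correlation pruning."""

import numpy as np
import pytest
from scipy import stats

from ctradiomics import screening


class TestBestThresholdBinary:
    def test_perfect_separation_at_unique_gap(self):
        values = np.arange(1, 11, dtype=float)
        labels = (values > 5).astype(int)
        res = screening.best_threshold_binary(values, labels)
        assert res.threshold == pytest.approx(5.5)
        ref_stat, ref_p = stats.pearsonr((values > 5.5).astype(int), labels)
        assert res.p_value == pytest.approx(ref_p)
        assert res.n_low == 5 and res.n_high == 5

    def test_constant_covariate_rejected(self):
        with pytest.raises(screening.DegenerateCovariateError):
            screening.best_threshold_binary(np.ones(10), np.tile([0, 1], 5))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(screening.DegenerateOutcomeError):
            screening.best_threshold_binary(np.arange(10.0), np.zeros(10, int))

    @pytest.mark.parametrize("test", ["pearson", "mann_whitney"])
    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_scan_oracle(self, seed, test):
        rng = np.random.default_rng(seed)
        n = 30
        values = rng.normal(size=n)
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        res = screening.best_threshold_binary(values, labels, test=test)
        # independent scan: plain loop over midpoints, library test call
        v = np.sort(np.unique(values))
        best = (None, np.inf)
        for t in (v[:-1] + v[1:]) / 2:
            d = (values > t).astype(int)
            lo = (~(values > t)).sum()
            if lo < 0.1 * n or (n - lo) < 0.1 * n:
                continue
            if test == "pearson":
                p = stats.pearsonr(d, labels).pvalue
            else:
                p = stats.mannwhitneyu(d[labels == 0], d[labels == 1], alternative="two-sided").pvalue
            if p < best[1]:
                best = (t, p)
        assert res.threshold == pytest.approx(best[0])
        assert res.p_value == pytest.approx(best[1])


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = np.array([1.0, 2, 3, 4, 5])
        e = np.array([1, 0, 1, 1, 0])
        chi2, p = screening.logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_separated_groups(self):
        ta, ea = np.array([1.0, 2, 3]), np.ones(3, int)
        tb, eb = np.array([10.0, 20, 30]), np.ones(3, int)
        chi2, p = screening.logrank_test(ta, ea, tb, eb)
        # direct O-E / V accumulation over the six event times
        times = np.r_[ta, tb]
        group = np.r_[np.zeros(3), np.ones(3)]
        o_minus_e, var = 0.0, 0.0
        for t in sorted(times):
            at_risk = times >= t
            n, n1 = at_risk.sum(), (at_risk & (group == 0)).sum()
            d = 1
            o_minus_e += (1 if t in ta else 0) - d * n1 / n
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-12)

    def test_matches_lifelines_on_random_data(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(7)
        ta, tb = rng.exponential(10, 40), rng.exponential(14, 35)
        ea, eb = rng.integers(0, 2, 40), rng.integers(0, 2, 35)
        ea[0] = 1
        chi2, p = screening.logrank_test(ta, ea, tb, eb)
        ref = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_raises(self):
        with pytest.raises(screening.NoEventsError):
            screening.logrank_test([1.0], [0], [2.0], [0])


class TestBestThresholdSurvival:
    def test_disjoint_event_supports_split_at_gap(self):
        values = np.r_[np.arange(10.0), 20 + np.arange(10.0)]
        times = np.r_[np.full(10, 2.0), np.full(10, 20.0)]
        events = np.ones(20, int)
        res = screening.best_threshold_survival(values, times, events)
        assert 9.0 < res.threshold < 20.0

    def test_tie_rule_returns_smallest_threshold(self):
        # both groups identical across any split: all candidate p equal 1
        values = np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        times = np.full(8, 5.0)
        events = np.ones(8, int)
        res = screening.best_threshold_survival(values, times, events)
        assert res.threshold == pytest.approx(1.5)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(40 + seed)
        n = 40
        values = rng.normal(size=n)
        hazard = np.where(values > np.median(values), 2.0, 0.5)
        times = rng.exponential(1.0 / hazard)
        events = (times < rng.exponential(2.0, n)).astype(int)
        if events.sum() == 0:
            events[0] = 1
        res = screening.best_threshold_survival(values, times, events)
        v = np.sort(np.unique(values))
        best = (None, np.inf)
        for t in (v[:-1] + v[1:]) / 2:
            hi = values > t
            if hi.sum() < 0.1 * n or (~hi).sum() < 0.1 * n:
                continue
            _, p = screening.logrank_test(times[~hi], events[~hi], times[hi], events[hi])
            if p < best[1]:
                best = (t, p)
        assert res.threshold == pytest.approx(best[0])
        assert res.p_value == pytest.approx(best[1])


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        km = screening.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert float(km.predict(3.0)) == pytest.approx(1.0)

    def test_closed_form_no_censoring(self):
        km = screening.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert float(km.predict(1.0)) == pytest.approx(2 / 3)
        assert float(km.predict(2.0)) == pytest.approx(1 / 3)
        assert float(km.predict(3.0)) == pytest.approx(0.0)

    def test_matches_independent_product_limit(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        e[:5] = 1
        km = screening.km_estimate(t, e)
        # hand-rolled product-limit estimator
        order = np.argsort(t)
        ts, es = t[order], e[order]
        s = 1.0
        surv = {}
        for i, (ti, ei) in enumerate(zip(ts, es)):
            at_risk = (ts >= ti).sum()
            if ei:
                d = ((ts == ti) & (es == 1)).sum()
                if ti not in surv:
                    s *= 1 - d / at_risk
                    surv[ti] = s
        for ti, si in surv.items():
            assert float(km.predict(ti)) == pytest.approx(si, rel=1e-9)


class TestPermutationAdjustedP:
    def test_null_signal_is_not_significant_after_adjustment(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[0] = 1 - labels[0] if labels.min() == labels.max() else labels[0]
        raw = screening.best_threshold_binary(values, labels).p_value
        adj = screening.permutation_adjusted_p(values, labels, n_permutations=100, seed=1)
        assert adj >= raw  # selection correction can only deflate significance

    def test_strong_signal_stays_significant(self):
        values = np.arange(40.0)
        labels = (values > 19.5).astype(int)
        adj = screening.permutation_adjusted_p(values, labels, n_permutations=100, seed=2)
        assert adj < 0.05


class TestCorrelationPrune:
    def test_edge_structure_forces_two_groups(self):
        rng = np.random.default_rng(0)
        n = 200
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        c = b + rng.normal(scale=0.1, size=n)  # b ~ c strongly correlated
        import pandas as pd

        df = pd.DataFrame({"A": a, "B": b, "C": c})
        groups, r, p = screening.correlation_prune(df, univariate_p={"A": 0.01, "B": 0.02, "C": 0.03})
        assert ["A", "B"] in groups and ["A", "C"] in groups
        assert not any("B" in g and "C" in g for g in groups)

    def test_independent_covariates_form_single_group(self):
        import pandas as pd

        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("wxyz"))
            groups, _, _ = screening.correlation_prune(df)
            if len(groups) == 1 and len(groups[0]) == 4:
                hits += 1
        assert hits >= 6  # false-positive edges at alpha=0.05 allowed occasionally

    def test_groups_are_internally_uncorrelated(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        z = rng.normal(size=(150, 3))
        df = pd.DataFrame(
            {
                "a": z[:, 0],
                "b": z[:, 0] + 0.3 * z[:, 1],
                "c": z[:, 1],
                "d": z[:, 2],
            }
        )
        groups, _, p = screening.correlation_prune(df)
        for g in groups:
            for i, x in enumerate(g):
                for y in g[i + 1 :]:
                    assert p.loc[x, y] >= 0.05

    def test_collinear_covariates_never_cooccur(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x1": x, "x2": 2 * x + 1, "y": rng.normal(size=100)})
        groups, _, _ = screening.correlation_prune(df)
        assert not any("x1" in g and "x2" in g for g in groups)
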