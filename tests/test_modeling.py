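"""Logistic/Cox models, the elastic-net path, ROC AUC and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctradiomics import modeling

from . import oracles


def _logistic_cohort(seed, n=300, k_noise=5, beta=np.log(5.0)):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, k_noise + 1)), columns=[f"x{i}" for i in range(k_noise + 1)])
    lp = beta * X["x0"]
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    return X, y


class TestLogisticBackward:
    def test_planted_effect_is_retained(self):
        hits = 0
        for seed in range(20):
            X, y = _logistic_cohort(seed)
            fit = modeling.logistic_backward(X, y)
            hits += "x0" in fit.covariates
        assert hits >= 16  # >= 80% of seeds

    def test_null_model_usually_empties(self):
        empty = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(rng.normal(size=(300, 5)), columns=list("abcde"))
            y = rng.integers(0, 2, 300)
            fit = modeling.logistic_backward(X, y)
            empty += len(fit.covariates) == 0
        assert empty >= 30  # >= 60% of runs

    def test_perfect_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.astype(int)
        fit = modeling.logistic_backward(pd.DataFrame({"x": x}), y)
        assert fit.flags.get("separation")

    def test_covariate_order_does_not_matter_without_ties(self):
        X, y = _logistic_cohort(3)
        f1 = modeling.logistic_backward(X, y)
        f2 = modeling.logistic_backward(X[list(reversed(X.columns))], y)
        assert sorted(f1.covariates) == sorted(f2.covariates)
        assert f1.auc == pytest.approx(f2.auc)


def _surv_cohort(seed, n=300, beta=(0.8, -0.8), k=20, censor_scale=2.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, k)), columns=[f"f{i}" for i in range(k)])
    lp = np.zeros(n)
    for b, c in zip(beta, X.columns):
        lp += b * X[c]
    t = rng.exponential(np.exp(-lp))
    c = rng.exponential(censor_scale, n)
    return X, np.minimum(t, c), (t <= c).astype(int)


class TestCoxFit:
    def test_hazard_ratio_recovery(self):
        rng = np.random.default_rng(0)
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / (0.1 * 2.0**x))
        c = rng.exponential(15.0, n)
        fit = modeling.cox_fit(pd.DataFrame({"x": x}), np.minimum(t, c), (t <= c).astype(int))
        hr = float(np.exp(fit.coef["x"]))
        assert 1.8 <= hr <= 2.2

    def test_null_wald_p_calibrated(self):
        cover = 0
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            n = 120
            x = rng.normal(size=n)
            t = rng.exponential(1.0, n)
            e = (t < rng.exponential(2.0, n)).astype(int)
            if e.sum() == 0:
                continue
            fit = modeling.cox_fit(pd.DataFrame({"x": x}), t, e)
            cover += fit.p_values["x"] > 0.05
        assert 90 <= cover <= 100  # ~95 of 100, +/- 5

    def test_zero_variance_covariate_excluded(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"const": np.ones(50), "x": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = modeling.cox_fit(X, rng.exponential(1, 50), np.ones(50, int))
        assert fit.covariates == ["x"]


class TestElasticNetPath:
    def test_full_shrinkage_at_top_of_grid(self):
        X, t, e = _surv_cohort(5, n=150, k=5)
        path = modeling.cox_elasticnet_path(X, t, e, n_folds=5, seed=1)
        assert np.allclose(path.coefs.iloc[:, 0].values, 0.0)
        assert path.lambda_1se >= path.lambda_min

    def test_small_lambda_limit_matches_unpenalized_cox(self):
        rng = np.random.default_rng(8)
        n = 400
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        t = rng.exponential(np.exp(-0.7 * X["a"]))
        e = np.ones(n, int)
        path = modeling.cox_elasticnet_path(X, t, e, mixing=1.0, n_folds=5, seed=0, alpha_min_ratio=1e-4)
        ref = modeling.cox_fit(X, t, e)
        near_zero = path.coefs.iloc[:, -1]  # smallest lambda on the grid
        assert near_zero["a"] == pytest.approx(ref.coef["a"], rel=0.01)

    def test_planted_signals_selected_at_lambda_1se(self):
        hits, fps = 0, []
        for seed in range(10):
            X, t, e = _surv_cohort(100 + seed)
            path = modeling.cox_elasticnet_path(X, t, e, n_folds=10, seed=seed)
            sel = set(path.selected)
            hits += {"f0", "f1"} <= sel
            fps.append(len(sel - {"f0", "f1"}))
        assert hits >= 8
        assert np.median(fps) <= 2

    def test_too_few_events_raises(self):
        X, t, e = _surv_cohort(0, n=30)
        with pytest.raises(ValueError, match="events"):
            modeling.cox_elasticnet_path(X, t, np.zeros_like(e) + (np.arange(30) < 3), n_folds=10)


class TestCoxStepwise:
    def test_null_covariate_eliminated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(3000 + seed)
            n = 250
            X = pd.DataFrame({"signal": rng.normal(size=n), "noise": rng.normal(size=n)})
            t = rng.exponential(np.exp(-1.0 * X["signal"]))
            e = np.ones(n, int)
            fit = modeling.cox_stepwise(X, t, e)
            hits += fit.covariates == ["signal"]
        assert hits >= 16

    def test_empty_offering_gives_null_model(self):
        rng = np.random.default_rng(0)
        fit = modeling.cox_stepwise(pd.DataFrame(index=range(50)), rng.exponential(1, 50), np.ones(50, int))
        assert fit.covariates == []
        assert fit.lr_stat == 0.0

    def test_single_strong_covariate_is_fixed_point(self):
        rng = np.random.default_rng(4)
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(np.exp(-X["x"]))
        e = np.ones(n, int)
        step = modeling.cox_stepwise(X, t, e)
        ref = modeling.cox_fit(X, t, e)
        assert step.coef["x"] == pytest.approx(ref.coef["x"], rel=1e-12)


class TestRocAuc:
    def test_perfect_and_tied_scores(self):
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        assert modeling.roc_auc(np.arange(10.0), y)[0] == pytest.approx(1.0)
        assert modeling.roc_auc(np.ones(10), y)[0] == pytest.approx(0.5)

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=12).round(1)  # rounding forces some ties
        labels = np.r_[np.ones(5, int), np.zeros(7, int)]
        auc, lo, hi = modeling.roc_auc(scores, labels)
        assert auc == pytest.approx(oracles.oracle_auc(scores, labels), abs=1e-12)
        assert lo <= auc <= hi

    def test_bootstrap_ci_brackets_auc(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        auc, lo, hi = modeling.roc_auc(scores, labels, ci_method="bootstrap", seed=1, n_boot=200)
        assert lo <= auc <= hi

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        a1 = modeling.roc_auc(scores, labels)[0]
        a2 = modeling.roc_auc(np.exp(3 * scores), labels)[0]
        assert a1 == pytest.approx(a2, abs=1e-12)


class TestHosmerLemeshow:
    def test_exact_agreement_gives_zero_statistic(self):
        # ten groups of 20, each with observed == expected exactly
        pred, y = [], []
        for k in range(10):
            p = (k + 1) / 20.0  # 0.05 .. 0.50 -> expected = 20p = k+1
            pred += [p] * 20
            y += [1] * (k + 1) + [0] * (20 - k - 1)
        chi2, pval, info = modeling.hosmer_lemeshow(np.array(pred), np.array(y))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_constant_predictions_flagged_degenerate(self):
        chi2, p, info = modeling.hosmer_lemeshow(np.full(40, 0.3), np.random.default_rng(0).integers(0, 2, 40))
        assert info["flags"].get("degenerate")
        assert np.isnan(p)


class TestCoxCalibration:
    def test_null_model_matches_pooled_km(self):
        rng = np.random.default_rng(21)
        n = 400
        X = pd.DataFrame({"x": rng.normal(size=n) * 1e-8})  # ~zero effect
        t = rng.exponential(10.0, n)
        e = (t < rng.uniform(1, 28, n)).astype(int)
        tt = np.minimum(t, 28.0)
        fit = modeling.cox_fit(X, tt, e)
        cal = modeling.cox_calibration(fit, horizons=(12.0,), n_risk_groups=3)
        from lifelines import KaplanMeierFitter

        pooled = float(KaplanMeierFitter().fit(tt, e).predict(12.0))
        for _, row in cal.iterrows():
            assert row["predicted_survival"] == pytest.approx(pooled, abs=0.1)

    def test_well_specified_model_calibrates(self):
        rng = np.random.default_rng(22)
        n = 500
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(12.0 * np.exp(-0.7 * X["x"]))
        c = rng.uniform(1, 28, n)
        fit = modeling.cox_fit(X, np.minimum(t, c), (t <= c).astype(int))
        cal = modeling.cox_calibration(fit, horizons=(12.0,), n_risk_groups=3)
        for _, row in cal.iterrows():
            assert abs(row["predicted_survival"] - row["observed_km_survival"]) <= 0.07

    def test_extrapolation_flag(self):
        rng = np.random.default_rng(23)
        n = 100
        X = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(2.0, n)
        fit = modeling.cox_fit(X, t, np.ones(n, int))
        cal = modeling.cox_calibration(fit, horizons=(t.max() + 10,), n_risk_groups=2)
        assert cal["extrapolated"].all()
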