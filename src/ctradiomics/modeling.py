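"""Multivariate outcome models and their evaluation.

Two model classes mirror the two endpoints of the analysis:

* binary response (local control): maximum-likelihood logistic regression
  with backward elimination of covariates whose Wald p exceeds
  ``alpha_stay``;
* overall survival: elastic-net-penalized Cox proportional hazards for
  variable selection (cross-validated partial-likelihood deviance, 1-SE
  rule), followed by backward stepwise Cox on the selected covariates.

Discrimination is summarized by the ROC AUC with a DeLong (default) or
bootstrap confidence interval; calibration by the Hosmer–Lemeshow test for
the logistic models and by risk-group predicted-vs-observed survival at
fixed horizons for the Cox model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelFit",
    "PenalizedPath",
    "logistic_backward",
    "cox_fit",
    "cox_elasticnet_path",
    "cox_stepwise",
    "roc_auc",
    "hosmer_lemeshow",
    "cox_calibration",
]


@dataclass
class ModelFit:
    """A fitted outcome model with its discrimination summary."""

    endpoint: str
    covariates: list[str]
    coef: pd.Series
    se: pd.Series
    p_values: pd.Series
    lr_stat: float
    lr_p: float
    auc: float
    auc_ci: tuple[float, float]
    scores: np.ndarray
    flags: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


@dataclass
class PenalizedPath:
    """Elastic-net Cox coefficient path with cross-validated deviance."""

    mixing: float
    lambdas: np.ndarray  # descending
    coefs: pd.DataFrame  # (covariate, lambda index), original scale
    cv_deviance_mean: np.ndarray
    cv_deviance_sd: np.ndarray  # standard error over folds, used by the 1-SE rule
    lambda_min: float
    lambda_1se: float
    selected: list[str]
    seed: int


# ---------------------------------------------------------------------------
# logistic regression with backward elimination


def _ridge_logistic(X: np.ndarray, y: np.ndarray, lam: float = 1e-3, n_iter: int = 100):
    """Newton IRLS for ridge-penalized logistic regression (separation fallback).

    Returns (beta, se) with the intercept unpenalized; SEs from the inverse
    penalized Hessian.
    """
    n, k = X.shape
    beta = np.zeros(k)
    pen = np.full(k, 2.0 * lam)
    pen[0] = 0.0  # intercept column
    for _ in range(n_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = p * (1 - p) + 1e-10
        h = X.T @ (X * w[:, None]) + np.diag(pen)
        g = X.T @ (y - p) - pen * beta
        step = np.linalg.solve(h, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    se = np.sqrt(np.diag(np.linalg.inv(h)))
    return beta, se


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """Fit one logistic model; returns (params, se, pvalues, llf, separated)."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            separated = bool(np.any(np.abs(res.params.values) > 15) or not np.isfinite(res.bse.values).all())
        except Exception:
            res = None
            separated = True
    if res is not None and not separated:
        return res.params, res.bse, res.pvalues, float(res.llf), False
    beta, se = _ridge_logistic(Xc.values.astype(float), y.astype(float))
    z = beta / se
    pv = 2 * stats.norm.sf(np.abs(z))
    eta = Xc.values @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    llf = float((y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
    idx = Xc.columns
    return pd.Series(beta, idx), pd.Series(se, idx), pd.Series(pv, idx), llf, True


def logistic_backward(
    X: pd.DataFrame,
    y,
    alpha_stay: float = 0.05,
    endpoint: str = "response",
) -> ModelFit:
    """Backward-elimination logistic regression.

    The full model is fitted by maximum likelihood; the covariate with the
    largest Wald p above ``alpha_stay`` is dropped and the model refitted
    until every retained covariate is significant or none remain
    (intercept-only).  Complete-quasi-separation is detected and handled with
    a small-ridge refit, flagged.  The model-level test is the likelihood
    ratio against the intercept-only model.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=int)
    mask = X.notna().all(axis=1) & np.isfinite(y)
    X, y = X.loc[mask], y[mask.values]
    if len(X) == 0:
        raise ValueError("no complete cases")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")

    flags: dict = {}
    cols = list(X.columns)
    while True:
        params, se, pv, llf, separated = _fit_logit(X[cols], y)
        if separated:
            flags["separation"] = True
        wald = pv.drop("const", errors="ignore")
        if len(wald) == 0 or wald.max() <= alpha_stay:
            break
        # drop the worst covariate; name order breaks exact p ties
        worst = wald[wald == wald.max()].index.sort_values()[0]
        cols.remove(worst)

    p0 = y.mean()
    ll0 = float((y * np.log(p0) + (1 - y) * np.log(1 - p0)).sum()) if 0 < p0 < 1 else 0.0
    lr = max(0.0, 2.0 * (llf - ll0))
    lr_p = float(stats.chi2.sf(lr, df=max(len(cols), 1))) if cols else 1.0

    import statsmodels.api as sm

    Xc = sm.add_constant(X[cols], has_constant="add")
    eta = Xc.values @ params.values
    scores = 1.0 / (1.0 + np.exp(-eta))
    if len(cols) > 0:
        auc, lo, hi = roc_auc(scores, y)
    else:
        auc, lo, hi = 0.5, 0.5, 0.5
    return ModelFit(
        endpoint=endpoint,
        covariates=cols,
        coef=params,
        se=se,
        p_values=pv,
        lr_stat=lr,
        lr_p=lr_p,
        auc=auc,
        auc_ci=(lo, hi),
        scores=scores,
        flags=flags,
        extras={"n": len(y), "llf": llf, "llnull": ll0},
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


def cox_fit(X: pd.DataFrame, times, events, endpoint: str = "survival") -> ModelFit:
    """Cox proportional-hazards fit (Efron tie handling, via lifelines).

    Zero-variance covariates are excluded with a warning; monotone-likelihood
    geometry (a covariate perfectly ordering the events) is flagged through
    the fitter's convergence diagnostics.  AUC uses vital status at last
    follow-up as the label and the linear predictor as the score.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceWarning

    X = pd.DataFrame(X).astype(float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    mask = X.notna().all(axis=1).values & np.isfinite(times) & np.isfinite(events)
    X, times, events = X.loc[mask], times[mask], events[mask]
    if events.sum() == 0:
        raise ValueError("no events observed")
    flags: dict = {}
    keep = [c for c in X.columns if X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    if dropped:
        warnings.warn(f"zero-variance covariates excluded: {dropped}")
        flags["dropped_constant"] = dropped
    df = X[keep].copy()
    df["time"] = times
    df["event"] = events
    cph = CoxPHFitter()
    if keep:
        with warnings.catch_warnings(record=True) as wrec:
            warnings.simplefilter("always")
            cph.fit(df, duration_col="time", event_col="event")
        if any(issubclass(w.category, ConvergenceWarning) for w in wrec):
            flags["monotone_likelihood"] = True
        coef = cph.params_
        se = cph.standard_errors_
        pv = cph.summary["p"]
        lr = cph.log_likelihood_ratio_test()
        lr_stat, lr_p = float(lr.test_statistic), float(lr.p_value)
        scores = cph.predict_log_partial_hazard(df).values.ravel()
    else:
        # null model: no partial-likelihood contribution beyond the baseline
        cph = None
        coef = pd.Series(dtype=float)
        se = pd.Series(dtype=float)
        pv = pd.Series(dtype=float)
        lr_stat, lr_p = 0.0, 1.0
        scores = np.zeros(len(df))
    if len(keep) and len(np.unique(events)) == 2:
        auc, lo, hi = roc_auc(scores, events)
    else:
        auc, lo, hi = 0.5, 0.5, 0.5
    return ModelFit(
        endpoint=endpoint,
        covariates=keep,
        coef=coef,
        se=se,
        p_values=pv,
        lr_stat=lr_stat,
        lr_p=lr_p,
        auc=auc,
        auc_ci=(lo, hi),
        scores=scores,
        flags=flags,
        extras={"fitter": cph, "n": len(df), "times": times, "events": events, "X": X[keep]},
    )


def _breslow_loglik(beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood (the quantity cross-validated below)."""
    eta = X @ beta
    order = np.argsort(-times, kind="stable")  # descending time
    eta_o, t_o, e_o = eta[order], times[order], events[order]
    cumexp = np.cumsum(np.exp(eta_o))
    # risk set at t_i = all with time >= t_i; ties share the same cumexp level
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        denom = cumexp[j - 1]
        for k in range(i, j):
            if e_o[k]:
                ll += eta_o[k] - np.log(denom)
        i = j
    return float(ll)


def cox_elasticnet_path(
    X: pd.DataFrame,
    times,
    events,
    mixing: float = 0.5,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    alpha_min_ratio: float = 0.01,
) -> PenalizedPath:
    """Elastic-net-regularized Cox coefficient path with k-fold CV deviance.

    Covariates are standardized to unit variance internally; the coefficient
    path (reported on the original scale) is computed over a descending
    log-spaced lambda grid.  Cross-validated partial-likelihood deviance uses
    the Verweij–van Houwelingen construction
    ``D_k = -2 (ll_all(beta_k) - ll_train_k(beta_k))``; ``lambda_min``
    minimizes the mean deviance and ``lambda_1se`` is the largest (sparsest)
    lambda within one standard error of that minimum.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    X = pd.DataFrame(X).astype(float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 covariates for a selection path")
    if events.sum() < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} events, got {int(events.sum())}")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Z = ((X - mu) / sd).values
    y = Surv.from_arrays(event=events, time=times)

    model = CoxnetSurvivalAnalysis(
        l1_ratio=mixing, n_alphas=n_lambdas, alpha_min_ratio=alpha_min_ratio, fit_baseline_model=False
    )
    model.fit(Z, y)
    lambdas = np.asarray(model.alphas_)
    coefs_std = model.coef_  # (p, n_lambdas)
    # the solver may stop the path early once the deviance saturates; pin the
    # requested grid minimum so the small-lambda limit is actually computed
    lam_target = float(lambdas[0] * alpha_min_ratio)
    if lambdas[-1] > lam_target * 1.001:
        tail = CoxnetSurvivalAnalysis(l1_ratio=mixing, alphas=[lam_target], fit_baseline_model=False)
        tail.fit(Z, y)
        lambdas = np.append(lambdas, lam_target)
        coefs_std = np.hstack([coefs_std, tail.coef_])

    # stratified fold assignment on event status, seeded
    rng = np.random.default_rng(seed)
    folds = np.empty(len(times), dtype=int)
    for val in (True, False):
        idx = np.flatnonzero(events == val)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    dev = np.zeros((n_folds, lambdas.size))
    for k in range(n_folds):
        tr = folds != k
        mk = CoxnetSurvivalAnalysis(l1_ratio=mixing, alphas=lambdas, fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mk.fit(Z[tr], y[tr])
        betas = np.zeros((Z.shape[1], lambdas.size))
        fitted = {a: i for i, a in enumerate(mk.alphas_)}
        for i, a in enumerate(lambdas):
            j = fitted.get(a)
            betas[:, i] = mk.coef_[:, j] if j is not None else mk.coef_[:, -1]
        for i in range(lambdas.size):
            b = betas[:, i]
            dev[k, i] = -2.0 * (
                _breslow_loglik(b, Z, times, events.astype(int))
                - _breslow_loglik(b, Z[tr], times[tr], events[tr].astype(int))
            )
    mean = dev.mean(axis=0)
    sdm = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean))
    lam_min = float(lambdas[i_min])
    within = np.flatnonzero(mean <= mean[i_min] + sdm[i_min])
    i_1se = int(within[np.argmax(lambdas[within])])
    lam_1se = float(lambdas[i_1se])
    coefs = pd.DataFrame(coefs_std / sd.values[:, None], index=X.columns)
    selected = list(coefs.index[np.abs(coefs_std[:, i_1se]) > 0])
    return PenalizedPath(
        mixing=mixing,
        lambdas=lambdas,
        coefs=coefs,
        cv_deviance_mean=mean,
        cv_deviance_sd=sdm,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        selected=selected,
        seed=seed,
    )


def cox_stepwise(
    X: pd.DataFrame,
    times,
    events,
    alpha_stay: float = 0.05,
    endpoint: str = "survival",
) -> ModelFit:
    """Backward stepwise Cox regression on Wald p-values.

    Intended to run on the covariates selected by the elastic-net stage; an
    empty offering yields the null model (LR statistic 0).
    """
    X = pd.DataFrame(X).astype(float)
    cols = list(X.columns)
    while True:
        fit = cox_fit(X[cols] if cols else pd.DataFrame(index=X.index), times, events, endpoint)
        if not fit.covariates:
            return fit
        pv = fit.p_values
        if pv.max() <= alpha_stay:
            return fit
        worst = pv[pv == pv.max()].index.sort_values()[0]
        cols.remove(worst)


# ---------------------------------------------------------------------------
# model evaluation


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank structural components."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rank_all = stats.rankdata(allv)
    rank_pos = stats.rankdata(pos)
    rank_neg = stats.rankdata(neg)
    v01 = (rank_all[:m] - rank_pos) / n  # per-positive components
    v10 = 1.0 - (rank_all[m:] - rank_neg) / m
    auc = v01.mean()
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def roc_auc(
    scores,
    labels,
    ci_method: str = "delong",
    seed: int = 0,
    n_boot: int = 2000,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """ROC AUC with a confidence interval.

    AUC is the pair-counting (Mann–Whitney) probability with ties counted
    1/2.  The CI is DeLong (default) or a seeded stratified bootstrap.
    Returns ``(auc, ci_lo, ci_hi)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    auc, var = _delong_variance(scores, labels)
    if ci_method == "delong":
        z = stats.norm.ppf(0.5 + level / 2)
        sd = np.sqrt(var)
        return float(auc), float(max(0.0, auc - z * sd)), float(min(1.0, auc + z * sd))
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        ipos = np.flatnonzero(labels == 1)
        ineg = np.flatnonzero(labels == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bi = np.concatenate([rng.choice(ipos, ipos.size), rng.choice(ineg, ineg.size)])
            reps[b], _ = _delong_variance(scores[bi], labels[bi])
        lo, hi = np.quantile(reps, [(1 - level) / 2, 0.5 + level / 2])
        return float(auc), float(lo), float(hi)
    raise ValueError(f"unknown ci_method {ci_method!r}")


def hosmer_lemeshow(pred, y, n_groups: int = 10) -> tuple[float, float, dict]:
    """Hosmer–Lemeshow goodness-of-fit test on deciles of predicted risk.

    Groups with tied prediction quantiles are merged (df adjusted, flagged).
    Returns ``(chi_square, p, info)`` with ``info`` carrying the group table;
    p > 0.05 indicates no significant departure from calibration.
    """
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(pred) < 2 * n_groups:
        raise ValueError(f"need at least {2 * n_groups} cases")
    if np.any((pred <= 0) | (pred >= 1)):
        pred = np.clip(pred, 1e-10, 1 - 1e-10)
    try:
        grp = pd.qcut(pred, n_groups, labels=False, duplicates="drop")
        grp = np.asarray(grp, dtype=float)
        if np.any(np.isnan(grp)):
            grp = np.zeros(len(pred))
    except ValueError:
        grp = np.zeros(len(pred))
    grp = grp.astype(int)
    g = int(np.unique(grp).size)
    info: dict = {"n_groups": g, "flags": {}}
    if g < n_groups:
        info["flags"]["merged_groups"] = True
    if g < 3:
        info["flags"]["degenerate"] = True
        return 0.0, float("nan"), info
    rows = []
    chi2 = 0.0
    for k in np.unique(grp):
        sel = grp == k
        nk = int(sel.sum())
        ok = int(y[sel].sum())
        pk = float(pred[sel].mean())
        ek = nk * pk
        chi2 += (ok - ek) ** 2 / (ek * (1 - pk)) if 0 < pk < 1 else 0.0
        rows.append({"n": nk, "observed": ok, "expected": ek, "mean_pred": pk})
    df = g - 2
    info["table"] = rows
    info["df"] = df
    return float(chi2), float(stats.chi2.sf(chi2, df=df)), info


def cox_calibration(
    fit: ModelFit,
    horizons=(12.0, 24.0),
    n_risk_groups: int = 3,
) -> pd.DataFrame:
    """Predicted vs observed survival at fixed horizons, by risk group.

    Cases are split into ``n_risk_groups`` by the Cox linear predictor; per
    group the mean model-predicted survival (Breslow baseline) at each
    horizon is compared with the group Kaplan–Meier estimate.  Horizons past
    the last observed time are flagged as extrapolation.
    """
    from lifelines import KaplanMeierFitter

    cph = fit.extras["fitter"]
    times = fit.extras["times"]
    events = fit.extras["events"]
    X = fit.extras["X"]
    lp = np.asarray(fit.scores, dtype=float)
    n = len(lp)
    if np.unique(lp).size >= n_risk_groups:
        grp = pd.qcut(lp, n_risk_groups, labels=False, duplicates="drop")
    else:
        grp = np.zeros(n, dtype=int)
    tmax = float(np.max(times))
    surv = cph.predict_survival_function(X, times=list(horizons))
    rows = []
    for k in np.unique(grp):
        sel = np.asarray(grp == k)
        km = KaplanMeierFitter().fit(times[sel], events[sel])
        for h in horizons:
            pred_s = float(surv.loc[h].values[sel].mean())
            obs_s = float(km.predict(h))
            rows.append(
                {
                    "risk_group": int(k),
                    "horizon": float(h),
                    "n": int(sel.sum()),
                    "predicted_survival": pred_s,
                    "observed_km_survival": obs_s,
                    "extrapolated": bool(h > tmax),
                }
            )
    return pd.DataFrame(rows)
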