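"""End-to-end orchestration: univariate screening -> pruning -> models.

The stage order follows the analysis design: mobile-threshold univariate
screening per endpoint, cross-correlation pruning of the significant
covariates, then per-group logistic models (binary response) and an
elastic-net + stepwise Cox model (survival), each evaluated for
discrimination and calibration.  Every artifact is written as CSV or JSON
with deterministic formatting, so config-identical reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import modeling, screening

__all__ = ["RunConfig", "run_pipeline", "CLINICAL_COVARIATES"]

CLINICAL_COVARIATES = (
    "age",
    "sex_female",
    "pv_thrombosis",
    "tumor_location",
    "ajcc_stage",
    "bclc_stage",
    "okuda_stage",
    "child_pugh_b",
    "hepatitis",
    "afp",
    "total_dose",
    "tumor_volume",
)


@dataclass
class RunConfig:
    """Serializable configuration for one pipeline run."""

    endpoints: tuple[str, ...] = ("response", "survival")
    alpha: float = 0.05
    min_frac: float = 0.10
    binary_test: str = "pearson"
    alpha_stay: float = 0.05
    enet_mixing: float = 0.5
    enet_folds: int = 10
    seed: int = 0
    horizons: tuple[float, float] = (12.0, 24.0)
    n_risk_groups: int = 3
    max_model_covariates: int = 12

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(path: str, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _covariate_columns(cohort: pd.DataFrame) -> list[str]:
    reserved = {"id", "response", "time", "event"}
    return [c for c in cohort.columns if c not in reserved and not c.endswith("_valid")]


def _modelfit_summary(fit: modeling.ModelFit) -> dict:
    return {
        "endpoint": fit.endpoint,
        "covariates": list(fit.covariates),
        "coef": {k: float(v) for k, v in fit.coef.items()},
        "se": {k: float(v) for k, v in fit.se.items()},
        "p_values": {k: float(v) for k, v in fit.p_values.items()},
        "lr_stat": float(fit.lr_stat),
        "lr_p": float(fit.lr_p),
        "auc": float(fit.auc),
        "auc_ci": [float(fit.auc_ci[0]), float(fit.auc_ci[1])],
        "flags": fit.flags,
        "n": int(fit.extras.get("n", 0)),
    }


def _screen_endpoint(df: pd.DataFrame, covs: list[str], endpoint: str, cfg: RunConfig, log: list[str]):
    """Mobile-threshold screening of every covariate against one endpoint."""
    rows = []
    for name in covs:
        sub_cols = [name, "response"] if endpoint == "response" else [name, "time", "event"]
        sub = df[sub_cols].dropna()
        n_omitted = len(df) - len(sub)
        if n_omitted:
            log.append(f"{endpoint}/{name}: omitted {n_omitted} cases with missing values")
        try:
            if endpoint == "response":
                res = screening.best_threshold_binary(
                    sub[name].values, sub["response"].values.astype(int),
                    test=cfg.binary_test, min_frac=cfg.min_frac, name=name,
                )
            else:
                res = screening.best_threshold_survival(
                    sub[name].values, sub["time"].values, sub["event"].values,
                    min_frac=cfg.min_frac, name=name,
                )
        except (screening.DegenerateCovariateError, screening.DegenerateOutcomeError, screening.NoEventsError) as e:
            log.append(f"{endpoint}/{name}: skipped ({e})")
            continue
        row = {
            "covariate": name,
            "threshold": res.threshold,
            "p_value": res.p_value,
            "statistic": res.statistic,
            "test": res.test,
            "n_low": res.n_low,
            "n_high": res.n_high,
        }
        if endpoint == "survival":
            # univariate hazard ratio of the dichotomized covariate
            from lifelines import CoxPHFitter

            d = (sub[name].values > res.threshold).astype(float)
            cdf = pd.DataFrame({"x": d, "time": sub["time"].values, "event": sub["event"].values})
            try:
                cph = CoxPHFitter().fit(cdf, "time", "event")
                row["hr"] = float(np.exp(cph.params_["x"]))
                row["hr_ci_low"] = float(np.exp(cph.confidence_intervals_.iloc[0, 0]))
                row["hr_ci_high"] = float(np.exp(cph.confidence_intervals_.iloc[0, 1]))
            except Exception:
                row["hr"] = float("nan")
        rows.append(row)
    tab = pd.DataFrame(rows).sort_values(["p_value", "covariate"], kind="stable").reset_index(drop=True)
    return tab


def run_pipeline(cohort: pd.DataFrame, config: RunConfig, out_dir: str, plots: bool = False) -> dict:
    """Run screening and modelling on a cohort table; write the report bundle.

    Returns a manifest dict listing every artifact.  Artifacts: univariate
    tables per endpoint, correlation (r, p) matrices, uncorrelated covariate
    groups, per-group logistic model summaries, the survival model (penalized
    path summary + final Cox fit), and calibration tables.
    """
    os.makedirs(out_dir, exist_ok=True)
    log: list[str] = []
    manifest: dict = {"config": config.to_dict(), "config_hash": config.hash(), "artifacts": [], "errors": {}}
    covs = _covariate_columns(cohort)

    def emit(name: str, obj) -> None:
        path = os.path.join(out_dir, name)
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=False)
        else:
            _write_json(path, obj)
        manifest["artifacts"].append(name)

    if "response" in config.endpoints:
        if "response" not in cohort.columns:
            raise KeyError("endpoint 'response' requested but cohort has no 'response' column")
        rd = cohort.dropna(subset=["response"])
        if len(rd) < len(cohort):
            log.append(
                f"response: omitted {len(cohort) - len(rd)} cases without response assessment "
                "(restricted dataset)"
            )
        uni = _screen_endpoint(rd, covs, "response", config, log)
        emit("univariate_response.csv", uni)
        sig = uni[uni["p_value"] <= config.alpha]["covariate"].tolist()
        sig = sig[: config.max_model_covariates]
        if len(sig) >= 2:
            upv = dict(zip(uni["covariate"], uni["p_value"]))
            groups, r, p = screening.correlation_prune(rd[sig], alpha=config.alpha, univariate_p=upv)
            emit("correlation_response_r.csv", r.reset_index(names="covariate"))
            emit("correlation_response_p.csv", p.reset_index(names="covariate"))
            emit("groups_response.json", {"groups": groups})
        else:
            groups = [sig] if sig else []
            emit("groups_response.json", {"groups": groups})
        thr = dict(zip(uni["covariate"], uni["threshold"]))
        models = []
        for gi, grp in enumerate(groups, start=1):
            if not grp:
                continue
            sub = rd[grp + ["response"]].dropna()
            X = pd.DataFrame({c: (sub[c].values > thr[c]).astype(float) for c in grp})
            try:
                fit = modeling.logistic_backward(X, sub["response"].values.astype(int), config.alpha_stay)
            except ValueError as e:
                manifest["errors"][f"response_model_{gi}"] = str(e)
                continue
            summ = _modelfit_summary(fit)
            if fit.covariates:
                chi2, hl_p, hl_info = modeling.hosmer_lemeshow(fit.scores, sub["response"].values.astype(int), n_groups=min(10, len(sub) // 2))
                summ["hosmer_lemeshow"] = {"chi_square": chi2, "p": hl_p, "flags": hl_info.get("flags", {})}
            summ["thresholds"] = {c: float(thr[c]) for c in grp}
            emit(f"model_response_group{gi}.json", summ)
            models.append(summ)

    if "survival" in config.endpoints:
        for col in ("time", "event"):
            if col not in cohort.columns:
                raise KeyError(f"endpoint 'survival' requested but cohort has no '{col}' column")
        fd = cohort.dropna(subset=["time", "event"])
        uni = _screen_endpoint(fd, covs, "survival", config, log)
        emit("univariate_survival.csv", uni)
        sig = uni[uni["p_value"] <= config.alpha]["covariate"].tolist()
        sig = sig[: config.max_model_covariates]
        if len(sig) >= 2:
            upv = dict(zip(uni["covariate"], uni["p_value"]))
            _, r, p = screening.correlation_prune(fd[sig], alpha=config.alpha, univariate_p=upv)
            emit("correlation_survival_r.csv", r.reset_index(names="covariate"))
            emit("correlation_survival_p.csv", p.reset_index(names="covariate"))
            sub = fd[sig + ["time", "event"]].dropna()
            path = modeling.cox_elasticnet_path(
                sub[sig], sub["time"].values, sub["event"].values,
                mixing=config.enet_mixing, n_folds=config.enet_folds, seed=config.seed,
            )
            emit(
                "enet_path_survival.json",
                {
                    "mixing": path.mixing,
                    "lambda_min": path.lambda_min,
                    "lambda_1se": path.lambda_1se,
                    "selected": path.selected,
                    "lambdas": path.lambdas,
                    "cv_deviance_mean": path.cv_deviance_mean,
                    "cv_deviance_sd": path.cv_deviance_sd,
                    "seed": path.seed,
                },
            )
            offered = path.selected if path.selected else sig
        else:
            offered = sig
            sub = fd[sig + ["time", "event"]].dropna() if sig else fd
        if offered:
            fit = modeling.cox_stepwise(sub[offered], sub["time"].values, sub["event"].values, config.alpha_stay)
            summ = _modelfit_summary(fit)
            summ["hr"] = {k: float(np.exp(v)) for k, v in fit.coef.items()}
            emit("model_survival.json", summ)
            if fit.covariates:
                cal = modeling.cox_calibration(fit, horizons=config.horizons, n_risk_groups=config.n_risk_groups)
                emit("calibration_survival.csv", cal)
            if plots:
                _survival_plots(out_dir, path if len(sig) >= 2 else None, fit, config, manifest)
        else:
            emit("model_survival.json", {"endpoint": "survival", "covariates": [], "note": "no significant covariates"})

    manifest["log"] = log
    _write_json(os.path.join(out_dir, "manifest.json"), manifest)
    return manifest


def _survival_plots(out_dir: str, path, fit, config: RunConfig, manifest: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(np.log(path.lambdas), path.cv_deviance_mean, "-o", ms=2)
        ax.fill_between(
            np.log(path.lambdas),
            path.cv_deviance_mean - path.cv_deviance_sd,
            path.cv_deviance_mean + path.cv_deviance_sd,
            alpha=0.3,
        )
        ax.axvline(np.log(path.lambda_min), ls=":", c="k")
        ax.axvline(np.log(path.lambda_1se), ls=":", c="r")
        ax.set_xlabel("log lambda")
        ax.set_ylabel("CV partial-likelihood deviance")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "enet_deviance.png"), dpi=120)
        plt.close(fig)
        manifest["artifacts"].append("enet_deviance.png")
    if fit.covariates:
        cal = modeling.cox_calibration(fit, horizons=config.horizons, n_risk_groups=config.n_risk_groups)
        fig, ax = plt.subplots(figsize=(5, 4))
        for h, grp in cal.groupby("horizon"):
            ax.plot(grp["predicted_survival"], grp["observed_km_survival"], "o-", label=f"{h:g} months")
        lim = [0, 1]
        ax.plot(lim, lim, "k:", lw=1)
        ax.set_xlabel("predicted survival")
        ax.set_ylabel("observed (KM) survival")
        ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "calibration_survival.png"), dpi=120)
        plt.close(fig)
        manifest["artifacts"].append("calibration_survival.png")
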