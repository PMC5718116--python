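"""Synthetic lesions and cohorts for pipeline testing.

No patient imaging or outcome data is distributed with this package; this
module generates (a) 3D lesion phantoms with controllable shape and texture
and (b) cohort tables whose clinical marginals, outcome links and censoring
emulate a 138-patient HCC radiotherapy series (median overall survival near
10 months, response evaluable in a 106-patient subset).

Two feature routes are provided: full voxel-level phantoms fed through the
feature extractor (used to validate extraction), and a fast feature-level
shortcut drawing the feature panel from a correlated Gaussian surrogate
model (used for statistical tests, where only the joint distribution and
the planted outcome links matter).  Everything is deterministic given the
seed, and every generating parameter is emitted in a ground-truth sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, special

from .features import FEATURE_NAMES, ExtractionConfig, extract_all
from .volume import ROIMask, VoxelVolume

__all__ = [
    "PhantomSpec",
    "OutcomeModelSpec",
    "generate_lesion",
    "generate_cohort",
    "emit_ground_truth",
    "regenerate_cohort",
    "CLINICAL_MARGINALS",
]

#: Target marginal structure of the emulated cohort (fractions / moments).
CLINICAL_MARGINALS: dict = {
    "sex_female": 0.188,
    "pv_thrombosis": 0.536,
    "tumor_location": {"right": 0.413, "left": 0.072, "bilateral": 0.514},
    "ajcc_stage": {1: 0.051, 2: 0.065, 3: 0.601, 4: 0.283},
    "okuda_stage": {1: 0.224, 2: 0.776},
    "bclc_stage": {1: 0.065, 2: 0.210, 3: 0.725},  # A/B/C
    "child_pugh_b": 0.304,
    "hepatitis": 0.862,
    "age_mean": 64.0,
    "age_sd": 11.0,
    "age_range": (30.0, 87.0),
    "total_dose": {54.0: 0.116, 60.0: 0.826, 66.0: 0.058},
}


@dataclass
class PhantomSpec:
    """Recipe for one synthetic lesion volume."""

    grid_shape: tuple[int, int, int] = (48, 48, 24)
    spacing: tuple[float, float, float] = (0.8, 0.8, 3.0)
    shape_family: str = "ellipsoid"  # or "lobulated"
    radii_mm: tuple[float, float, float] = (14.0, 12.0, 16.0)
    lobulation: float = 0.0  # in [0, 1): radial perturbation amplitude
    intensity_mean: float = 60.0
    intensity_sd: float = 12.0
    correlation_length: float = 1.5  # voxels; 0 = white noise
    skew: float = 0.0  # in [0, 1): weight of a skewed intensity component
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lobulation < 1):
            raise ValueError("lobulation must lie in [0, 1)")
        if self.correlation_length < 0:
            raise ValueError("correlation_length must be >= 0")
        if not (0 <= self.skew < 1):
            raise ValueError("skew must lie in [0, 1)")


@dataclass
class OutcomeModelSpec:
    """Planted outcome links and censoring for a synthetic cohort.

    Coefficients act on standardized (generating-scale) covariates.  The
    exponential baseline scale is calibrated so the marginal median survival
    equals ``target_median_os`` months under the planted hazard effects.
    """

    response_intercept: float = 0.6
    response_log_odds: dict[str, float] = field(default_factory=lambda: {"energy_H": 1.2})
    baseline: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.0
    target_median_os: float = 10.1
    survival_log_hr: dict[str, float] = field(
        default_factory=lambda: {"compacity": -1.5, "bclc_stage": 0.3}
    )
    censor_admin_months: float = 28.0
    censor_min_months: float = 1.0
    response_missing_handled_by_subset: bool = True


# ---------------------------------------------------------------------------
# lesion phantoms


def _radial_modulation(theta: np.ndarray, phi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth random function on the sphere, normalized to max |.| = 1.

    A random combination of real spherical harmonics of degree 1..3 gives a
    lobulated but smooth boundary perturbation.
    """
    g = np.zeros_like(theta)
    for ell in range(1, 4):
        for m in range(-ell, ell + 1):
            c = rng.normal() / (1 + ell)
            y = special.sph_harm_y(ell, abs(m), theta, phi)
            g += c * (y.real if m >= 0 else y.imag)
    peak = np.max(np.abs(g))
    return g / peak if peak > 0 else g


def generate_lesion(spec: PhantomSpec) -> tuple[VoxelVolume, ROIMask]:
    """Generate one lesion volume and mask from a :class:`PhantomSpec`.

    The mask is a digitized (possibly radially perturbed) ellipsoid; interior
    intensities come from a stationary correlated Gaussian field (smoothed
    white noise) optionally mixed with an exponential component that skews
    the histogram.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    dx, dy, dz = spec.spacing
    cx, cy, cz = ((n - 1) / 2 for n in spec.grid_shape)
    x = (np.arange(nx) - cx)[:, None, None] * dx
    y = (np.arange(ny) - cy)[None, :, None] * dy
    z = (np.arange(nz) - cz)[None, None, :] * dz
    a, b, c = spec.radii_mm
    if a > cx * dx or b > cy * dy or c > cz * dz:
        raise ValueError(f"lesion radii {spec.radii_mm} exceed grid half-extent")
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    if spec.shape_family == "lobulated" and spec.lobulation > 0:
        r = np.sqrt(x**2 + y**2 + z**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.divide(z, r, out=np.zeros_like(rho), where=r > 0), -1, 1))
        phi = np.arctan2(y, x) + np.pi
        g = _radial_modulation(theta, phi, rng)
        mask = rho <= 1.0 + spec.lobulation * g
    elif spec.shape_family in ("ellipsoid", "lobulated"):
        mask = rho <= 1.0
    else:
        raise ValueError(f"unknown shape family {spec.shape_family!r}")

    noise = rng.standard_normal(spec.grid_shape)
    if spec.correlation_length > 0:
        noise = ndimage.gaussian_filter(noise, sigma=spec.correlation_length, mode="reflect")
    noise = (noise - noise.mean()) / (noise.std() + 1e-12)
    if spec.skew > 0:
        skew_field = rng.exponential(1.0, spec.grid_shape) - 1.0
        if spec.correlation_length > 0:
            skew_field = ndimage.gaussian_filter(skew_field, sigma=spec.correlation_length, mode="reflect")
        skew_field = (skew_field - skew_field.mean()) / (skew_field.std() + 1e-12)
        noise = (1 - spec.skew) * noise + spec.skew * skew_field
        noise = (noise - noise.mean()) / (noise.std() + 1e-12)
    data = spec.intensity_mean + spec.intensity_sd * noise
    vol = VoxelVolume(data, spec.spacing)
    return vol, ROIMask(mask)


# ---------------------------------------------------------------------------
# feature-level surrogate model

#: Generating mean / sd for the Gaussian feature surrogate (plausible scales
#: for a 64-level discretization of a mid-size lesion).
_FAMILY_OF: dict[str, str] = {}
for fam, names in {
    "shape": ("sphericity", "compacity"),
    "hist": ("skewness", "kurtosis", "entropy_H", "energy_H"),
    "glcm": (
        "glcm_homogeneity",
        "glcm_energy",
        "glcm_contrast",
        "glcm_correlation",
        "glcm_entropy",
        "glcm_dissimilarity",
    ),
    "ngldm": ("ngldm_contrast", "ngldm_coarseness"),
    "glrlm": ("SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GLNU_r", "RLNU", "RP"),
    "glzlm": ("SZE", "LZE", "LGZE", "HGZE", "SZLGE", "SZHGE", "LZLGE", "LZHGE", "GLNU_z", "ZLNU", "ZP"),
}.items():
    for _nm in names:
        _FAMILY_OF[_nm] = fam

_SURROGATE_LOC = {
    "sphericity": (0.85, 0.08),
    "compacity": (0.045, 0.012),
    "skewness": (0.5, 0.8),
    "kurtosis": (3.2, 0.8),
    "entropy_H": (4.5, 0.6),
    "energy_H": (0.06, 0.02),
    "glcm_homogeneity": (0.45, 0.08),
    "glcm_energy": (0.02, 0.01),
    "glcm_contrast": (35.0, 12.0),
    "glcm_correlation": (0.35, 0.15),
    "glcm_entropy": (7.0, 0.8),
    "glcm_dissimilarity": (4.2, 1.2),
    "ngldm_contrast": (0.1, 0.04),
    "ngldm_coarseness": (0.005, 0.002),
    "SRE": (0.93, 0.03),
    "LRE": (1.4, 0.25),
    "LGRE": (0.01, 0.004),
    "HGRE": (1500.0, 400.0),
    "SRLGE": (0.009, 0.003),
    "SRHGE": (1400.0, 380.0),
    "LRLGE": (0.015, 0.005),
    "LRHGE": (2100.0, 600.0),
    "GLNU_r": (180.0, 60.0),
    "RLNU": (5200.0, 1500.0),
    "RP": (0.9, 0.04),
    "SZE": (0.7, 0.08),
    "LZE": (60.0, 25.0),
    "LGZE": (0.012, 0.004),
    "HGZE": (1400.0, 380.0),
    "SZLGE": (0.008, 0.003),
    "SZHGE": (1000.0, 300.0),
    "LZLGE": (0.8, 0.3),
    "LZHGE": (90000.0, 30000.0),
    "GLNU_z": (25.0, 8.0),
    "ZLNU": (350.0, 120.0),
    "ZP": (0.35, 0.08),
}

#: latent correlation: within family 0.6, across families 0.1 (compacity and
#: energy_H — the planted drivers — kept free of cross-family correlation so
#: the selection stages see a clean signal)
_RHO_WITHIN = 0.6
_RHO_ACROSS = 0.1
_DECOUPLED = ("compacity", "energy_H")


def _feature_correlation() -> np.ndarray:
    k = len(FEATURE_NAMES)
    rho = np.full((k, k), _RHO_ACROSS)
    for i, a in enumerate(FEATURE_NAMES):
        for j, b in enumerate(FEATURE_NAMES):
            if i == j:
                rho[i, j] = 1.0
            elif _FAMILY_OF[a] == _FAMILY_OF[b]:
                rho[i, j] = _RHO_WITHIN
    for nm in _DECOUPLED:
        i = FEATURE_NAMES.index(nm)
        rho[i, :] = 0.0
        rho[:, i] = 0.0
        rho[i, i] = 1.0
    # ensure positive definiteness
    w, v = np.linalg.eigh(rho)
    w = np.clip(w, 1e-6, None)
    rho = v @ np.diag(w) @ v.T
    d = np.sqrt(np.diag(rho))
    return rho / np.outer(d, d)


def _draw_features(n: int, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw (features, standardized latents) from the Gaussian surrogate."""
    rho = _feature_correlation()
    chol = np.linalg.cholesky(rho)
    z = rng.standard_normal((n, len(FEATURE_NAMES))) @ chol.T
    zdf = pd.DataFrame(z, columns=FEATURE_NAMES)
    cols = {}
    for i, nm in enumerate(FEATURE_NAMES):
        mu, sd = _SURROGATE_LOC[nm]
        cols[nm] = mu + sd * z[:, i]
    return pd.DataFrame(cols), zdf


# ---------------------------------------------------------------------------
# outcome generation


def _calibrate_baseline_rate(outcome: OutcomeModelSpec) -> float:
    """Exponential rate such that marginal median survival hits the target.

    The linear predictor over standardized covariates is approximately
    N(mu_lp, sigma_lp^2); the marginal survival is integrated by
    Gauss–Hermite quadrature and the rate solved by bisection.
    """
    betas = np.asarray(list(outcome.survival_log_hr.values()), dtype=float)
    # clinical stage covariates are roughly unit-variance after coding; treat
    # every planted covariate as standard normal in the latent scale
    sigma = float(np.sqrt((betas**2).sum()))
    t = outcome.target_median_os
    nodes, weights = np.polynomial.hermite_e.hermegauss(64)
    weights = weights / weights.sum()

    def marginal_surv(rate: float) -> float:
        return float((weights * np.exp(-rate * np.exp(sigma * nodes) * t)).sum())

    if sigma == 0:
        return float(np.log(2.0) / t)
    return float(optimize.brentq(lambda r: marginal_surv(r) - 0.5, 1e-6, 10.0, xtol=1e-12))


def _ordered_draw(rng, n: int, dist: dict) -> np.ndarray:
    keys = list(dist.keys())
    probs = np.asarray([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=n, p=probs)
    vals = np.asarray([float(k) if not isinstance(k, str) else i for i, k in enumerate(keys)], dtype=float)
    return vals[idx]


def _draw_clinical(n: int, rng: np.random.Generator) -> pd.DataFrame:
    m = CLINICAL_MARGINALS
    age = np.clip(rng.normal(m["age_mean"], m["age_sd"], n), *m["age_range"])
    loc_keys = list(m["tumor_location"])
    loc_p = np.asarray(list(m["tumor_location"].values()), dtype=float)
    loc = rng.choice(len(loc_keys), n, p=loc_p / loc_p.sum())
    afp = np.minimum(np.exp(rng.normal(5.5, 2.5, n)) + 2.4, 58300.0)  # heavy-tailed, range-limited
    return pd.DataFrame(
        {
            "age": age,
            "sex_female": (rng.random(n) < m["sex_female"]).astype(int),
            "pv_thrombosis": (rng.random(n) < m["pv_thrombosis"]).astype(int),
            "tumor_location": loc,
            "ajcc_stage": _ordered_draw(rng, n, m["ajcc_stage"]),
            "okuda_stage": _ordered_draw(rng, n, m["okuda_stage"]),
            "bclc_stage": _ordered_draw(rng, n, m["bclc_stage"]),
            "child_pugh_b": (rng.random(n) < m["child_pugh_b"]).astype(int),
            "hepatitis": (rng.random(n) < m["hepatitis"]).astype(int),
            "afp": afp,
            "total_dose": _ordered_draw(rng, n, m["total_dose"]),
            "tumor_volume": np.exp(rng.normal(11.0, 0.8, n)),  # mm^3, ~60 cm^3 median
        }
    )


def _standardize_for_links(cohort: pd.DataFrame, latents: pd.DataFrame, name: str) -> np.ndarray:
    """Standardized covariate used by the planted links.

    Features use their exact latent standard-normal score; clinical columns
    are standardized empirically.
    """
    if name in latents.columns:
        return latents[name].values
    x = cohort[name].values.astype(float)
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_cohort(
    n_total: int = 138,
    n_response_subset: int = 106,
    outcome: OutcomeModelSpec | None = None,
    seed: int = 0,
    phantom_specs: list[PhantomSpec] | None = None,
    extraction_config: ExtractionConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table with planted feature–outcome links.

    Clinical covariates approximate the emulated marginals; the feature panel
    comes either from per-patient phantom volumes (``phantom_specs``) or from
    the Gaussian surrogate model.  Binary response follows the logistic model
    on the response subset (missing elsewhere); survival times follow the
    calibrated baseline hazard with planted log-hazard-ratios and uniform
    administrative censoring.  Returns ``(cohort, truth)`` where ``truth``
    is the JSON-serializable ground-truth sidecar.
    """
    if n_response_subset > n_total:
        raise ValueError("n_response_subset must not exceed n_total")
    outcome = outcome or OutcomeModelSpec()
    rng = np.random.default_rng(seed)
    clinical = _draw_clinical(n_total, rng)

    if phantom_specs is not None:
        if len(phantom_specs) != n_total:
            raise ValueError("need one PhantomSpec per patient")
        rows = []
        for spec in phantom_specs:
            vol, msk = generate_lesion(spec)
            rows.append(extract_all(vol, msk, extraction_config).values)
        feats = pd.DataFrame(rows)
        latents = (feats - feats.mean()) / feats.std(ddof=0).replace(0.0, 1.0)
        feature_route = "phantom"
    else:
        feats, latents = _draw_features(n_total, rng)
        feature_route = "surrogate"

    cohort = pd.concat([clinical, feats], axis=1)
    cohort.insert(0, "id", [f"P{i:04d}" for i in range(n_total)])

    # binary response on the evaluable subset
    lp_resp = np.full(n_total, outcome.response_intercept, dtype=float)
    for nm, b in outcome.response_log_odds.items():
        lp_resp += b * _standardize_for_links(cohort, latents, nm)
    p_resp = 1.0 / (1.0 + np.exp(-lp_resp))
    response = (rng.random(n_total) < p_resp).astype(float)
    evaluable = rng.choice(n_total, size=n_response_subset, replace=False)
    resp_col = np.full(n_total, np.nan)
    resp_col[evaluable] = response[evaluable]
    cohort["response"] = resp_col

    # survival with planted hazard effects and administrative censoring
    lp_surv = np.zeros(n_total)
    for nm, b in outcome.survival_log_hr.items():
        lp_surv += b * _standardize_for_links(cohort, latents, nm)
    rate0 = _calibrate_baseline_rate(outcome)
    u = rng.random(n_total)
    if outcome.baseline == "weibull":
        t_event = (-np.log(u) / np.exp(lp_surv)) ** (1.0 / outcome.weibull_shape) / rate0
    else:
        t_event = -np.log(u) / (rate0 * np.exp(lp_surv))
    censor = rng.uniform(outcome.censor_min_months, outcome.censor_admin_months, n_total)
    cohort["time"] = np.minimum(t_event, censor)
    cohort["event"] = (t_event <= censor).astype(int)

    truth = {
        "generator": "ctradiomics.synthetic.generate_cohort",
        "seed": int(seed),
        "n_total": int(n_total),
        "n_response_subset": int(n_response_subset),
        "feature_route": feature_route,
        "outcome": asdict(outcome),
        "baseline_rate_per_month": rate0,
        "clinical_marginals": json.loads(json.dumps(CLINICAL_MARGINALS, default=str)),
        "surrogate": {
            "loc": {k: list(v) for k, v in _SURROGATE_LOC.items()},
            "rho_within_family": _RHO_WITHIN,
            "rho_across_family": _RHO_ACROSS,
            "decoupled": list(_DECOUPLED),
        },
    }
    return cohort, truth


def emit_ground_truth(truth: dict, path: str) -> None:
    """Write the ground-truth sidecar as deterministic JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def regenerate_cohort(truth: dict) -> pd.DataFrame:
    """Rebuild the cohort table from a ground-truth sidecar (exact replay)."""
    outcome = OutcomeModelSpec(**truth["outcome"])
    cohort, _ = generate_cohort(
        n_total=truth["n_total"],
        n_response_subset=truth["n_response_subset"],
        outcome=outcome,
        seed=truth["seed"],
    )
    return cohort
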