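"""Univariate screening: mobile-threshold dichotomization and pruning.

A continuous covariate is screened against a binary endpoint (objective
response / local control) or a right-censored survival endpoint by scanning
every admissible cut-point — the midpoints between consecutive sorted
distinct values — and keeping the cut with the smallest test p-value
("mobile threshold").  The scan is exhaustive; no approximation.  Selected
p-values are reported raw (no correction for the threshold search), with an
optional permutation-adjusted p available as a labelled extension.

Covariates surviving screening are pruned into groups of mutually
uncorrelated covariates: pairwise Pearson tests define a correlation graph
(edge when p < alpha) and groups are maximal independent sets grown greedily
in order of ascending univariate p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdResult",
    "best_threshold_binary",
    "best_threshold_survival",
    "logrank_test",
    "km_estimate",
    "correlation_prune",
    "permutation_adjusted_p",
]


class DegenerateCovariateError(ValueError):
    """All covariate values identical: no admissible split exists."""


class DegenerateOutcomeError(ValueError):
    """All outcome labels identical."""


class NoEventsError(ValueError):
    """No events observed: survival tests are undefined."""


@dataclass
class ThresholdResult:
    """Optimal cut-point of one covariate with its selection p-value."""

    covariate: str
    threshold: float
    p_value: float
    statistic: float
    test: str
    n_low: int
    n_high: int
    extras: dict = field(default_factory=dict)


def _candidate_thresholds(values: np.ndarray, min_frac: float) -> np.ndarray:
    """Midpoints of consecutive sorted distinct values whose induced split
    leaves at least ``min_frac * n`` cases on each side."""
    v = np.sort(np.unique(values))
    if v.size < 2:
        raise DegenerateCovariateError("covariate has fewer than 2 distinct values")
    mids = (v[:-1] + v[1:]) / 2.0
    n = values.size
    min_n = min_frac * n
    keep = []
    for t in mids:
        lo = int((values <= t).sum())
        if lo >= min_n and (n - lo) >= min_n:
            keep.append(t)
    if not keep:
        raise DegenerateCovariateError(
            f"no admissible split at min_frac={min_frac} (n={n}, {v.size} distinct values)"
        )
    return np.asarray(keep)


def best_threshold_binary(
    values,
    labels,
    test: str = "pearson",
    min_frac: float = 0.10,
    name: str = "covariate",
) -> ThresholdResult:
    """Exhaustive mobile-threshold scan against a binary endpoint.

    ``test='pearson'`` correlates the dichotomized covariate with the 0/1
    labels (equivalent to the phi coefficient / 1-df chi-square);
    ``'mann_whitney'`` compares the dichotomized covariate between label
    groups.  Ties in p are broken toward the smaller threshold.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise DegenerateOutcomeError("both outcome classes must be present")
    cands = _candidate_thresholds(values, min_frac)
    best = None
    for t in cands:  # ascending: strict < keeps the smaller threshold on ties
        d = (values > t).astype(int)
        if test == "pearson":
            stat, p = stats.pearsonr(d, labels)
        elif test == "mann_whitney":
            res = stats.mannwhitneyu(d[labels == 0], d[labels == 1], alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown test {test!r}")
        if best is None or p < best[1]:
            best = (t, float(p), float(stat))
    t, p, stat = best
    n_lo = int((values <= t).sum())
    return ThresholdResult(name, float(t), p, stat, test, n_lo, values.size - n_lo)


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    Observed-minus-expected events accumulated over the pooled distinct event
    times with hypergeometric variance terms; p from chi-square with 1 df.
    Returns ``(chi_square, p)``.
    """
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise NoEventsError("no events in either group")
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    group = np.concatenate([np.zeros(ta.size, dtype=int), np.ones(tb.size, dtype=int)])
    ev_times = np.unique(times[events == 1])
    # at-risk and event counts at each distinct event time
    n_j = (times[None, :] >= ev_times[:, None]).sum(axis=1).astype(float)
    n1_j = ((times[None, :] >= ev_times[:, None]) & (group[None, :] == 0)).sum(axis=1).astype(float)
    d_j = ((times[None, :] == ev_times[:, None]) & (events[None, :] == 1)).sum(axis=1).astype(float)
    d1_j = (
        ((times[None, :] == ev_times[:, None]) & (events[None, :] == 1) & (group[None, :] == 0))
        .sum(axis=1)
        .astype(float)
    )
    exp1 = d_j * n1_j / n_j
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d_j * (n1_j / n_j) * (1.0 - n1_j / n_j) * (n_j - d_j) / (n_j - 1.0)
    var = np.where(n_j > 1, var, 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0, 1.0
    chi2 = (d1_j.sum() - exp1.sum()) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def best_threshold_survival(
    values,
    times,
    events,
    min_frac: float = 0.10,
    name: str = "covariate",
) -> ThresholdResult:
    """Mobile-threshold scan with the two-group log-rank p as criterion."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise NoEventsError("no events observed")
    cands = _candidate_thresholds(values, min_frac)
    best = None
    for t in cands:
        hi = values > t
        chi2, p = logrank_test(times[~hi], events[~hi], times[hi], events[hi])
        if best is None or p < best[1]:
            best = (t, p, chi2)
    t, p, chi2 = best
    n_lo = int((values <= t).sum())
    return ThresholdResult(name, float(t), p, chi2, "logrank", n_lo, values.size - n_lo)


def km_estimate(times, events):
    """Kaplan–Meier product-limit survival curve.

    Returns a :class:`lifelines.KaplanMeierFitter`; ``predict(t)`` evaluates
    the right-continuous step function, ``median_survival_time_`` the median.
    """
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=int))
    return km


def correlation_prune(
    feature_matrix: pd.DataFrame,
    alpha: float = 0.05,
    univariate_p: dict[str, float] | None = None,
) -> tuple[list[list[str]], pd.DataFrame, pd.DataFrame]:
    """Group covariates into maximal mutually uncorrelated sets.

    Pairwise Pearson r and test p are computed on complete cases; covariates
    are "cross-related" when p < alpha.  Starting from each covariate in
    ascending order of its univariate screening p (name order fallback), a
    group is grown greedily by adding covariates with no edge into the group;
    duplicate and subset groups are discarded.

    Returns ``(groups, r_matrix, p_matrix)``.
    """
    df = feature_matrix.dropna()
    if df.shape[1] < 2:
        raise ValueError("need at least 2 covariates")
    if df.shape[0] < 4:
        raise ValueError("need at least 4 complete cases")
    cols = [c for c in df.columns if df[c].nunique() > 1]
    dropped = [c for c in df.columns if c not in cols]
    if dropped:
        import warnings

        warnings.warn(f"constant covariates excluded from pruning: {dropped}")
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    edge = {c: set() for c in cols}
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi = stats.pearsonr(df[cols[i]], df[cols[j]])
            r.iloc[i, j] = r.iloc[j, i] = ri
            p.iloc[i, j] = p.iloc[j, i] = pi
            if pi < alpha:
                edge[cols[i]].add(cols[j])
                edge[cols[j]].add(cols[i])
    if univariate_p:
        order = sorted(cols, key=lambda c: (univariate_p.get(c, np.inf), c))
    else:
        order = sorted(cols)
    groups: list[list[str]] = []
    seen: set[frozenset] = set()
    for seed in order:
        grp = [seed]
        for c in order:
            if c != seed and not edge[c].intersection(grp):
                grp.append(c)
        key = frozenset(grp)
        if key not in seen and not any(key < g for g in seen):
            seen = {g for g in seen if not g < key}
            seen.add(key)
            groups.append(sorted(grp, key=order.index))
    return groups, r, p


def permutation_adjusted_p(
    values,
    labels_or_times,
    events=None,
    n_permutations: int = 200,
    min_frac: float = 0.10,
    seed: int = 0,
    test: str = "pearson",
) -> float:
    """Selection-adjusted p for the mobile-threshold minimum (extension).

    The raw selected p-value ignores the multiplicity of the threshold scan;
    this permutation test re-runs the full scan on outcome-permuted data and
    reports the fraction of permutations achieving a smaller or equal minimal
    p.  Not part of the baseline screening output.
    """
    rng = np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    if events is None:
        obs = best_threshold_binary(values, labels_or_times, test=test, min_frac=min_frac).p_value
    else:
        obs = best_threshold_survival(values, labels_or_times, events, min_frac=min_frac).p_value
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(values.size)
        if events is None:
            p = best_threshold_binary(values, np.asarray(labels_or_times)[perm], test=test, min_frac=min_frac).p_value
        else:
            p = best_threshold_survival(
                values, np.asarray(labels_or_times)[perm], np.asarray(events)[perm], min_frac=min_frac
            ).p_value
        if p <= obs:
            hits += 1
    return (hits + 1) / (n_permutations + 1)
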