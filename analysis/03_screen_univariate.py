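#!/usr/bin/env python
"""Univariate mobile-threshold screening of the simulated cohort.

For each covariate the exhaustive cut-point scan reports the threshold with
the smallest test p-value — Pearson test against binary response on the
restricted dataset, log-rank against survival on the full dataset —
followed by cross-correlation pruning of the significant covariates.
Requires 01_simulate_cohort.py to have run.
"""

import os

import pandas as pd

from ctradiomics.pipeline import RunConfig, run_pipeline

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main() -> None:
    cohort = pd.read_csv(os.path.join(BASE, "cohort", "cohort.csv"))
    out = os.path.join(BASE, "screening")
    cfg = RunConfig(seed=17)
    run_pipeline(cohort, cfg, out)

    for endpoint in ("response", "survival"):
        uni = pd.read_csv(os.path.join(out, f"univariate_{endpoint}.csv"))
        sig = uni[uni["p_value"] <= cfg.alpha]
        print(f"{endpoint}: {len(sig)}/{len(uni)} covariates significant at alpha={cfg.alpha}")
        cols = ["covariate", "threshold", "p_value"] + (["hr"] if "hr" in uni.columns and endpoint == "survival" else [])
        print(sig.head(8)[cols].round(4).to_string(index=False))
        print()
    print(f"screening artifacts (tables, correlation matrices, groups) in {os.path.normpath(out)}")


if __name__ == "__main__":
    main()
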