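#!/usr/bin/env python
"""Group comparisons: mixed-effects K-Score models and pain-measure ANCOVAs.

Fits the heteroskedastic random-intercept model K-Score ~ cohort x repetition
for each landmark set, with max-|t|-adjusted per-repetition contrasts, and
compares PASS-20, PROMIS-PI and both PPT sites between LBP-F and LBP-M by
rank ANCOVA correcting for age and BMI. Requires results/kscores.csv and
results/covariates.csv (run 01 and 02 first); regenerates them if absent.
"""

import argparse
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from kscore.pipeline import RunConfig, stats_stage
from kscore.stats import check_normality

ROOT = Path(__file__).resolve().parents[1]


def ensure_inputs(seed):
    results = ROOT / "results"
    if not (results / "kscores.csv").exists():
        for script in ("01_simulate_cohort.py", "02_fit_and_score.py"):
            subprocess.run(
                [sys.executable, str(ROOT / "analysis" / script),
                 "--seed", str(seed)],
                check=True,
            )
    return (
        pd.read_csv(results / "kscores.csv"),
        pd.read_csv(results / "covariates.csv"),
    )


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    cfg = RunConfig(seed=args.seed)
    table, covariates = ensure_inputs(args.seed)

    stat, p = check_normality(table["kscore"])
    print(f"Shapiro-Wilk on pooled K-Scores: W={stat:.3f}, p={p:.2e} "
          f"-> rank-based path for pain measures")

    mixed, ancova, _ = stats_stage(cfg, table, covariates)
    results = ROOT / "results"

    summary_rows, contrast_rows = [], []
    for name, res in mixed.items():
        cm = res.cell_means.copy()
        cm.insert(0, "landmark_set", name)
        summary_rows.append(cm)
        for c in res.contrasts:
            contrast_rows.append(dict(
                landmark_set=name, contrast=c.label, estimate=c.estimate,
                se=c.se, p_raw=c.p_raw, p_adjusted=c.p_adjusted,
            ))
        print(f"\n{name}: interaction LRT chi2={res.interaction_stat:.2f} "
              f"(df={res.interaction_df}, p={res.interaction_p:.3f}); "
              f"sigma_b={res.random_intercept_sd:.2f}, "
              f"residual SD {dict((k, round(v, 2)) for k, v in res.residual_sd.items())}")
        fm = [c for c in res.contrasts if "LBP-F - LBP-M" in c.label]
        for c in fm:
            print(f"  {c.label}: {c.estimate:+.2f} (SE {c.se:.2f}), "
                  f"adj p = {c.p_adjusted:.4f}")
    pd.concat(summary_rows, ignore_index=True).to_csv(
        results / "kscore_summary.csv", index=False
    )
    pd.DataFrame(contrast_rows).to_csv(
        results / "kscore_contrasts.csv", index=False
    )

    print("\nLBP-F vs LBP-M pain measures (rank ANCOVA, age+BMI adjusted):")
    ancova_rows = []
    for measure, res in ancova.items():
        mi = res.extra["median_iqr"]
        line = ", ".join(f"{lv}: {v[0]:.1f} +/- {v[1]:.1f}" for lv, v in mi.items())
        print(f"  {measure}: {line}; p = {res.p_raw:.2e}")
        ancova_rows.append(dict(measure=measure, p=res.p_raw, **{
            f"median_iqr_{lv}": f"{v[0]:.1f} +/- {v[1]:.1f}" for lv, v in mi.items()
        }))
    pd.DataFrame(ancova_rows).to_csv(results / "pain_ancova.csv", index=False)
    print(f"\nwrote {results / 'kscore_summary.csv'}, "
          f"{results / 'kscore_contrasts.csv'}, {results / 'pain_ancova.csv'}")


if __name__ == "__main__":
    main()
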