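#!/usr/bin/env python
"""Pain-biomechanics regressions on repetition-averaged trunk K-Scores.

One OLS model per pain measure (PASS-20, PROMIS-PI, pain-site PPT) with
Spearman-rank-transformed predictors (pain measure, age, BMI) and the
trunk K-Score averaged over repetitions 2-5 as the outcome, on the LBP
cohort; the PPT model is additionally stratified by sex. R^2 is labeled
with the weak (< 0.16) / moderate / strong (> 0.36) taxonomy.
"""

import argparse
import subprocess
import sys
from pathlib import Path

import pandas as pd

from kscore.stats import (
    attach_ppt_sites,
    regress_pain_on_kscore,
    subject_mean_kscores,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    results = ROOT / "results"
    if not (results / "kscores.csv").exists():
        for script in ("01_simulate_cohort.py", "02_fit_and_score.py"):
            subprocess.run(
                [sys.executable, str(ROOT / "analysis" / script),
                 "--seed", str(args.seed)],
                check=True,
            )
    table = pd.read_csv(results / "kscores.csv")
    subjects = attach_ppt_sites(pd.read_csv(results / "covariates.csv"))
    lbp = subjects[subjects.group == "LBP"]
    trunk_means = subject_mean_kscores(
        table[table.subject_id.isin(lbp.subject_id)], "trunk"
    )

    rows = []
    for measure in ("pass20", "promis_pi", "ppt_pain_site"):
        res = regress_pain_on_kscore(trunk_means, lbp, measure)["all"]
        rows.append(dict(model=measure, **_fields(res)))
        print(f"tK ~ rank({measure}) + rank(age) + rank(bmi): "
              f"R2 = {res.r_squared:.3f} ({res.strength}), "
              f"pain slope {res.slope:+.3f}, p = {res.p_value:.3f}, n = {res.n}")
    for sex, res in regress_pain_on_kscore(
        trunk_means, lbp, "ppt_pain_site", stratify_sex=True
    ).items():
        rows.append(dict(model=f"ppt_pain_site[{sex}]", **_fields(res)))
        print(f"  {sex} stratum: R2 = {res.r_squared:.3f} ({res.strength}), "
              f"slope {res.slope:+.3f}, p = {res.p_value:.3f}, n = {res.n}")

    pd.DataFrame(rows).to_csv(results / "pain_regressions.csv", index=False)
    print(f"wrote {results / 'pain_regressions.csv'}")


def _fields(res):
    return dict(
        n=res.n, r_squared=res.r_squared, p_value=res.p_value,
        slope=res.slope, strength=res.strength,
    )


if __name__ == "__main__":
    main()
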