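#!/usr/bin/env python
"""Simulate the default synthetic cohort and write its data files.

Generates 62 pain-free controls and 110 female / 84 male chronic low-back-
pain patients, each with a five-repetition sit-to-stand session at 30 Hz and
a pseudo-clinical covariate record (age, BMI, PASS-20, PROMIS-PI, three PPT
readings per site). Small artifacts (covariates, provenance manifest) go to
results/; the raw trajectory file is large (~60 MB) and goes to scratch/.
"""

import argparse
from pathlib import Path

from kscore.mocap_io import write_trajectories
from kscore.pipeline import RunConfig, simulate_stage
from kscore.simulate import write_manifest
from kscore.stats import attach_ppt_sites, summarize_median_iqr

ROOT = Path(__file__).resolve().parents[1]


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = RunConfig(seed=args.seed)
    trajectories, covariates, manifest = simulate_stage(cfg)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    covariates.to_csv(results / "covariates.csv", index=False)
    write_manifest(manifest, results / "cohort_manifest.json")
    scratch = ROOT / "scratch" / "sim"
    scratch.mkdir(parents=True, exist_ok=True)
    write_trajectories(trajectories, scratch / "trajectories.csv")

    print(f"simulated {len(covariates)} subjects "
          f"({(covariates.group == 'CTRL').sum()} CTRL, "
          f"{((covariates.group == 'LBP') & (covariates.sex == 'F')).sum()} LBP-F, "
          f"{((covariates.group == 'LBP') & (covariates.sex == 'M')).sum()} LBP-M)")
    with_sites = attach_ppt_sites(covariates)
    lbp = with_sites[with_sites.group == "LBP"]
    for site in ("control", "pain"):
        for sex in ("F", "M"):
            med, iqr = summarize_median_iqr(
                lbp.loc[lbp.sex == sex, f"ppt_{site}_site"]
            )
            print(f"  LBP-{sex} PPT {site} site: {med:.0f} +/- {iqr:.0f} kPa")
    print(f"wrote {results / 'covariates.csv'}")
    print(f"wrote {results / 'cohort_manifest.json'}")
    print(f"wrote {scratch / 'trajectories.csv'}")


if __name__ == "__main__":
    main()
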