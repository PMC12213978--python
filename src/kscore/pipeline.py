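"""End-to-end reproducible runs: simulate -> segment -> fit -> score -> analyze.

A run is a pure function of its :class:`RunConfig`: one master seed feeds the
cohort generator, every stage writes its artifact under the output directory,
and re-running the same config reproduces all numeric outputs byte for byte.
Output files carry the config hash in a leading comment line; the run
manifest records per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mocap_io, scoring, simulate, stats
from .errors import KScoreError, PipelineError
from .landmarks import FULL_BODY, LOWER_EXTREMITY, TRUNK

logger = logging.getLogger(__name__)

LANDMARK_SET_NAMES = ("full_body", "trunk", "lower_extremity")
_SETS = {"full_body": FULL_BODY, "trunk": TRUNK, "lower_extremity": LOWER_EXTREMITY}


@dataclass
class RunConfig:
    """Serializable configuration of one full pipeline run."""

    seed: int = 12345
    cohort: simulate.CohortConfig = field(default_factory=simulate.CohortConfig)
    segmentation: mocap_io.SegmentationParams = field(
        default_factory=mocap_io.SegmentationParams
    )
    grid_size: int = 101
    variance_threshold: float = 0.90
    beta: float = 25.0
    deviation_norm: str = "l1"
    allow_scaling: bool = False
    adjustment: str = "max-t"
    write_trajectories: bool = False  # the raw motion file is large
    pain_measures: tuple = ("pass20", "promis_pi", "ppt_pain_site")

    def __post_init__(self):
        # a single master seed drives the cohort stage
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["groups"] = {
            "|".join(k): asdict(v) for k, v in self.cohort.groups.items()
        }
        d["cohort"]["ppt"] = {
            "|".join(k): list(v) for k, v in self.cohort.ppt.items()
        }
        d["pain_measures"] = list(self.pain_measures)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            cd = dict(d["cohort"])
            if "groups" in cd:
                cd["groups"] = {
                    tuple(k.split("|")): simulate.GroupDistributions(**v)
                    for k, v in cd["groups"].items()
                }
            if "ppt" in cd:
                cd["ppt"] = {
                    tuple(k.split("|")): tuple(v) for k, v in cd["ppt"].items()
                }
            for key in ("pass20_beta", "promis_beta", "stature"):
                if key in cd:
                    cd[key] = {k: tuple(v) for k, v in cd[key].items()}
            d["cohort"] = simulate.CohortConfig(**cd)
        if "segmentation" in d:
            d["segmentation"] = mocap_io.SegmentationParams(**d["segmentation"])
        if "pain_measures" in d:
            d["pain_measures"] = tuple(d["pain_measures"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def cohort_label(group: str, sex: str) -> str:
    """CTRL, LBP-F or LBP-M — the grouping used in all published contrasts."""
    return "CTRL" if group == "CTRL" else f"LBP-{sex}"


# ---------------------------------------------------------------------------
# Stages (importable individually by the analysis scripts)
# ---------------------------------------------------------------------------

def simulate_stage(config: RunConfig):
    trajectories, covariates, manifest = simulate.generate_cohort(config.cohort)
    return trajectories, covariates, manifest


def normalize_stage(config: RunConfig, trajectories):
    """Segment, drop the first repetition, and time-normalize per landmark set."""
    trials_by_set: dict[str, list] = {name: [] for name in LANDMARK_SET_NAMES}
    for traj in trajectories:
        reps = mocap_io.drop_first_repetition(
            mocap_io.segment_sts(traj, config.segmentation)
        )
        for name in LANDMARK_SET_NAMES:
            trials_by_set[name].extend(
                mocap_io.time_normalize(
                    rep, _SETS[name], config.grid_size, subject_id=traj.subject_id
                )
                for rep in reps
            )
    return trials_by_set


def fit_stage(config: RunConfig, trials_by_set, covariates: pd.DataFrame):
    ctrl_ids = set(covariates.loc[covariates["group"] == "CTRL", "subject_id"])
    if len(ctrl_ids) < 3:
        raise PipelineError(
            "fit_reference",
            f"need >= 3 control subjects to fit the reference models, "
            f"got {len(ctrl_ids)}",
        )
    control_by_set = {
        name: [t for t in trials if t.subject_id in ctrl_ids]
        for name, trials in trials_by_set.items()
    }
    return scoring.fit_all_references(
        control_by_set,
        variance_threshold=config.variance_threshold,
        beta=config.beta,
        deviation_norm=config.deviation_norm,
        allow_scaling=config.allow_scaling,
    )


def score_stage(config: RunConfig, trials_by_set, models, covariates):
    all_trials = [t for trials in trials_by_set.values() for t in trials]
    table = scoring.score_cohort(
        all_trials, models, covariates, allow_scaling=config.allow_scaling
    )
    table["cohort"] = [
        cohort_label(g, s) for g, s in zip(table["group"], table["sex"])
    ]
    return table


def stats_stage(config: RunConfig, kscore_table: pd.DataFrame,
                covariates: pd.DataFrame):
    """Mixed models per landmark set, sex ANCOVAs, pain regressions."""
    subjects = stats.attach_ppt_sites(covariates)
    lbp = subjects[subjects["group"] == "LBP"]

    mixed = {}
    for name in LANDMARK_SET_NAMES:
        sub = kscore_table[kscore_table["landmark_set"] == name]
        mixed[name] = stats.fit_kscore_model(
            sub, group_col="cohort", adjustment=config.adjustment
        )

    ancova = {}
    for measure in ("pass20", "promis_pi", "ppt_control_site", "ppt_pain_site"):
        ancova[measure] = stats.rank_ancova(
            lbp[measure], lbp["sex"], lbp["age_years"], lbp["bmi"],
            label=measure,
        )

    lbp_ids = set(lbp["subject_id"])
    trunk_means = stats.subject_mean_kscores(
        kscore_table[kscore_table["subject_id"].isin(lbp_ids)], "trunk"
    )
    regressions = {}
    for measure in config.pain_measures:
        regressions[measure] = stats.regress_pain_on_kscore(
            trunk_means, lbp, measure
        )["all"]
    stratified = stats.regress_pain_on_kscore(
        trunk_means, lbp, "ppt_pain_site", stratify_sex=True
    )
    for sex, res in stratified.items():
        regressions[f"ppt_pain_site[{sex}]"] = res
    return mixed, ancova, regressions


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _stage(name: str, fn, *args):
    try:
        return fn(*args)
    except PipelineError:
        raise
    except KScoreError as err:
        raise PipelineError(name, str(err)) from err


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute all stages, writing every artifact under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    counts: dict[str, int] = {}
    config.to_yaml(out / "run_config.yaml")

    trajectories, covariates, manifest = _stage(
        "simulate", simulate_stage, config
    )
    counts["subjects"] = len(covariates)
    simulate.write_manifest(manifest, out / "cohort_manifest.json")
    _write_csv(covariates, out / "covariates.csv", h)
    if config.write_trajectories:
        mocap_io.write_trajectories(trajectories, out / "trajectories.csv")
    logger.info("simulate: %d subjects", counts["subjects"])

    trials_by_set = _stage("normalize", normalize_stage, config, trajectories)
    counts["normalized_trials"] = sum(len(v) for v in trials_by_set.values())
    logger.info("normalize: %d trials", counts["normalized_trials"])

    models = _stage("fit_reference", fit_stage, config, trials_by_set, covariates)
    (out / "models").mkdir(exist_ok=True)
    for name, model in models.items():
        model.to_json(out / "models" / f"{name}.json")
    counts["models"] = len(models)

    table = _stage("score", score_stage, config, trials_by_set, models, covariates)
    _write_csv(table, out / "kscores.csv", h)
    counts["kscore_rows"] = len(table)
    logger.info("score: %d rows", counts["kscore_rows"])

    mixed, ancova, regressions = _stage(
        "analyze", stats_stage, config, table, covariates
    )
    summary_rows, contrast_rows = [], []
    for name, res in mixed.items():
        cm = res.cell_means.copy()
        cm.insert(0, "landmark_set", name)
        summary_rows.append(cm)
        for c in res.contrasts:
            contrast_rows.append(dict(
                landmark_set=name, contrast=c.label, estimate=c.estimate,
                se=c.se, p_raw=c.p_raw, p_adjusted=c.p_adjusted,
                adjustment=c.adjustment,
            ))
        contrast_rows.append(dict(
            landmark_set=name,
            contrast="group x repetition interaction (LRT)",
            estimate=res.interaction_stat, se=np.nan,
            p_raw=res.interaction_p, p_adjusted=res.interaction_p,
            adjustment=f"chi2 df={res.interaction_df}",
        ))
    _write_csv(pd.concat(summary_rows, ignore_index=True),
               out / "kscore_summary.csv", h)
    _write_csv(pd.DataFrame(contrast_rows), out / "kscore_contrasts.csv", h)

    ancova_rows = [
        dict(
            measure=m, contrast=r.label, estimate=r.estimate, se=r.se,
            p=r.p_adjusted,
            **{
                f"median_iqr_{lv}": f"{mi[0]:.1f} +/- {mi[1]:.1f}"
                for lv, mi in r.extra["median_iqr"].items()
            },
        )
        for m, r in ancova.items()
    ]
    _write_csv(pd.DataFrame(ancova_rows), out / "pain_ancova.csv", h)

    regression_rows = [
        dict(
            model=key, pain_measure=r.predictors[0], n=r.n,
            r_squared=r.r_squared, p_value=r.p_value, slope=r.slope,
            strength=r.strength,
        )
        for key, r in regressions.items()
    ]
    _write_csv(pd.DataFrame(regression_rows), out / "pain_regressions.csv", h)
    counts["ancova_results"] = len(ancova_rows)
    counts["regression_results"] = len(regression_rows)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(
            {"config_hash": h, "seed": config.seed, "counts": counts},
            fh, indent=1, sort_keys=True,
        )
    return out
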