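import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle_reference importable

from kscore.pipeline import (
    RunConfig,
    fit_stage,
    normalize_stage,
    score_stage,
    simulate_stage,
)


def small_config(seed=11, n_ctrl=10, n_f=12, n_m=12) -> RunConfig:
    cfg = RunConfig(seed=seed)
    cfg.cohort.n_ctrl = n_ctrl
    cfg.cohort.n_lbp_f = n_f
    cfg.cohort.n_lbp_m = n_m
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced cohort run shared by scoring/stats tests (fit is slow-ish)."""
    cfg = small_config()
    trajectories, covariates, manifest = simulate_stage(cfg)
    trials_by_set = normalize_stage(cfg, trajectories)
    models = fit_stage(cfg, trials_by_set, covariates)
    table = score_stage(cfg, trials_by_set, models, covariates)
    return dict(
        config=cfg,
        trajectories=trajectories,
        covariates=covariates,
        manifest=manifest,
        trials_by_set=trials_by_set,
        models=models,
        table=table,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(4242)
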