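"""Control-referenced movement-quality scoring.

The model is fit on healthy-control trials only. All control time points
(each row one normalized time point's flattened landmark coordinates) are
stacked, centered, and decomposed by PCA; the minimal number of components
whose cumulative explained variance reaches ``variance_threshold`` is
retained. Every trial becomes a ``grid_size x k`` trajectory in PC space and
is superimposed on the control-average PC trajectory (the reference
configuration) by ordinary Procrustes analysis — translation and rotation,
optional isotropic scaling (off by default so amplitude deficits are
penalized). Because the reference is fixed at the control average, alignment
is a single Procrustes fit to that reference rather than an iterative
round-robin, and scores stay consistent when patient data is added.

The K-Profile collapses the aligned PC trajectory to one curve per trial: the
per-time-point sum of PC scores weighted by retained explained-variance
ratios (renormalized to sum to 1). The K-Score maps the mean absolute
deviation D between a trial's K-Profile and the control-average profile onto
a 100-anchored scale::

    K = 100 * (1 - D / (beta * D_cal))

where ``D_cal`` is the mean deviation of the control trials themselves and
``beta`` a fixed shrink factor, so the control-average trajectory scores
exactly 100 and larger deviations score strictly lower (unbounded below).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from sklearn.decomposition import PCA

from .errors import (
    DegenerateInputError,
    ModelStateError,
    ParameterError,
)
from .landmarks import LandmarkSet, get_landmark_set
from .mocap_io import NormalizedTrial

logger = logging.getLogger(__name__)

EXPECTED_REPETITIONS = (2, 3, 4, 5)


@dataclass
class KProfile:
    """One trial's weighted-PC-score curve over normalized time."""

    subject_id: str
    repetition_index: int
    landmark_set: str
    values: np.ndarray


@dataclass
class ReferenceModel:
    """Fitted control reference: PCA basis, Procrustes target, calibration."""

    landmark_set: str
    grid_size: int
    column_means: np.ndarray          # (3*|set|,)
    basis: np.ndarray                 # k x (3*|set|), orthonormal rows
    weights: np.ndarray               # k, renormalized EVRs (sum 1)
    explained_variance_ratio: np.ndarray  # k, raw retained EVRs
    variance_threshold: float
    reference_config: np.ndarray      # grid_size x k
    reference_profile: np.ndarray     # grid_size
    d_cal: float | None = None
    beta: float = 25.0
    deviation_norm: str = "l1"
    n_control_trials: int = 0

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    # -- serialization -----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "format": "kscore-reference-model v1",
            "landmark_set": self.landmark_set,
            "grid_size": self.grid_size,
            "column_means": self.column_means.tolist(),
            "basis": self.basis.tolist(),
            "weights": self.weights.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "variance_threshold": self.variance_threshold,
            "reference_config": self.reference_config.tolist(),
            "reference_profile": self.reference_profile.tolist(),
            "d_cal": self.d_cal,
            "beta": self.beta,
            "deviation_norm": self.deviation_norm,
            "n_control_trials": self.n_control_trials,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ReferenceModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            landmark_set=payload["landmark_set"],
            grid_size=payload["grid_size"],
            column_means=np.asarray(payload["column_means"]),
            basis=np.asarray(payload["basis"]),
            weights=np.asarray(payload["weights"]),
            explained_variance_ratio=np.asarray(
                payload["explained_variance_ratio"]
            ),
            variance_threshold=payload["variance_threshold"],
            reference_config=np.asarray(payload["reference_config"]),
            reference_profile=np.asarray(payload["reference_profile"]),
            d_cal=payload["d_cal"],
            beta=payload["beta"],
            deviation_norm=payload["deviation_norm"],
            n_control_trials=payload["n_control_trials"],
        )


def _canonical_signs(basis: np.ndarray) -> np.ndarray:
    """Deterministic PC sign convention: largest-|loading| entry positive."""
    out = basis.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def _deviation(profile: np.ndarray, reference: np.ndarray, norm: str) -> float:
    diff = np.asarray(profile, dtype=float) - np.asarray(reference, dtype=float)
    if norm == "l1":
        return float(np.mean(np.abs(diff)))
    if norm == "l2":
        return float(np.sqrt(np.mean(diff**2)))
    raise ParameterError(f"unknown deviation norm {norm!r}")


def _check_trials(trials: Sequence[NormalizedTrial]) -> tuple[int, LandmarkSet]:
    grid_sizes = {t.grid_size for t in trials}
    sets = {t.landmark_set.name for t in trials}
    if len(grid_sizes) != 1 or len(sets) != 1:
        raise ParameterError(
            f"trials mix grid sizes {sorted(grid_sizes)} or landmark sets "
            f"{sorted(sets)}"
        )
    return grid_sizes.pop(), trials[0].landmark_set


def fit_reference(
    control_trials: Sequence[NormalizedTrial],
    variance_threshold: float = 0.90,
    beta: float = 25.0,
    deviation_norm: str = "l1",
    allow_scaling: bool = False,
) -> ReferenceModel:
    """Fit the control-referenced scoring model from normalized control trials.

    Calibration rule: ``d_cal`` is the mean profile deviation of the control
    trials themselves (each aligned to the control-average configuration), so
    the average control trial sits a fixed fraction ``1/beta`` of the scale
    below 100.
    """
    control_trials = list(control_trials)
    if len(control_trials) < 3:
        raise ParameterError(
            f"need >= 3 control trials to fit a reference, got {len(control_trials)}"
        )
    if not 0.0 < variance_threshold <= 1.0:
        raise ParameterError("variance_threshold must lie in (0, 1]")
    grid_size, lm_set = _check_trials(control_trials)

    stacked = np.vstack([t.coords for t in control_trials])
    if np.allclose(stacked.var(axis=0).sum(), 0.0):
        raise DegenerateInputError("control trials carry zero total variance")
    pca = PCA(svd_solver="full")
    pca.fit(stacked)
    evr = pca.explained_variance_ratio_
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    k = min(k, len(evr))
    basis = _canonical_signs(pca.components_[:k])
    column_means = pca.mean_
    retained_evr = evr[:k]
    weights = retained_evr / retained_evr.sum()

    projections = [
        (t.coords - column_means) @ basis.T for t in control_trials
    ]
    reference_config = np.mean(projections, axis=0)
    reference_profile = reference_config @ weights

    model = ReferenceModel(
        landmark_set=lm_set.name,
        grid_size=grid_size,
        column_means=column_means,
        basis=basis,
        weights=weights,
        explained_variance_ratio=retained_evr,
        variance_threshold=variance_threshold,
        reference_config=reference_config,
        reference_profile=reference_profile,
        beta=beta,
        deviation_norm=deviation_norm,
        n_control_trials=len(control_trials),
    )

    deviations = [
        _deviation(
            compute_kprofile(
                project_and_align(t, model, allow_scaling=allow_scaling), model
            ).values,
            reference_profile,
            deviation_norm,
        )
        for t in control_trials
    ]
    d_cal = float(np.mean(deviations))
    if d_cal <= 1e-12:
        raise DegenerateInputError(
            "control trials are numerically identical; deviation calibration "
            "is undefined"
        )
    model.d_cal = d_cal
    return model


def project_and_align(
    trial: NormalizedTrial | np.ndarray,
    model: ReferenceModel,
    allow_scaling: bool = False,
) -> np.ndarray:
    """Center, project onto the PC basis, and Procrustes-align to the reference.

    Accepts a NormalizedTrial or a raw ``grid_size x (3*|set|)`` coordinate
    matrix. Returns the aligned ``grid_size x k`` PC trajectory.
    """
    coords = trial.coords if isinstance(trial, NormalizedTrial) else np.asarray(trial)
    if coords.shape != (model.grid_size, model.column_means.size):
        raise ParameterError(
            f"trial shape {coords.shape} does not match model "
            f"({model.grid_size}, {model.column_means.size})"
        )
    config = (coords - model.column_means) @ model.basis.T
    return align_configuration(config, model.reference_config, allow_scaling)


def align_configuration(
    config: np.ndarray, reference: np.ndarray, allow_scaling: bool = False
) -> np.ndarray:
    """Ordinary Procrustes superimposition of one PC trajectory on another.

    Minimizes the summed squared distance to ``reference`` over translation
    and rotation (plus isotropic scaling when ``allow_scaling``).
    """
    config = np.asarray(config, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if config.shape != reference.shape:
        raise ParameterError(
            f"configuration shape {config.shape} != reference {reference.shape}"
        )
    mu_c = config.mean(axis=0)
    mu_r = reference.mean(axis=0)
    a = config - mu_c
    b = reference - mu_r
    rotation, cross = orthogonal_procrustes(a, b)
    scale = 1.0
    if allow_scaling:
        denom = float((a**2).sum())
        if denom > 0:
            scale = cross / denom
    return scale * a @ rotation + mu_r


def compute_kprofile(
    aligned: np.ndarray,
    model: ReferenceModel,
    subject_id: str = "",
    repetition_index: int = 0,
) -> KProfile:
    """Weighted sum of aligned PC scores at every normalized time point."""
    aligned = np.asarray(aligned, dtype=float)
    if aligned.shape != (model.grid_size, model.n_components):
        raise ParameterError(
            f"aligned trajectory shape {aligned.shape} does not match model "
            f"({model.grid_size}, {model.n_components})"
        )
    return KProfile(
        subject_id=subject_id,
        repetition_index=repetition_index,
        landmark_set=model.landmark_set,
        values=aligned @ model.weights,
    )


def compute_kscore(profile: KProfile | np.ndarray, model: ReferenceModel) -> float:
    """Map one K-Profile's deviation from the control average to the 100 scale."""
    if model.d_cal is None:
        raise ModelStateError("model has no deviation calibration (d_cal)")
    values = profile.values if isinstance(profile, KProfile) else np.asarray(profile)
    if values.shape != model.reference_profile.shape:
        raise ParameterError("profile length does not match model grid size")
    d = _deviation(values, model.reference_profile, model.deviation_norm)
    return 100.0 * (1.0 - d / (model.beta * model.d_cal))


def score_trial(
    trial: NormalizedTrial, model: ReferenceModel, allow_scaling: bool = False
) -> float:
    """Full per-trial path: center -> project -> align -> profile -> score."""
    aligned = project_and_align(trial, model, allow_scaling=allow_scaling)
    profile = compute_kprofile(
        aligned, model, trial.subject_id, trial.repetition_index
    )
    return compute_kscore(profile, model)


def score_cohort(
    trials: Iterable[NormalizedTrial],
    models: Mapping[str, ReferenceModel],
    subjects: pd.DataFrame,
    allow_scaling: bool = False,
) -> pd.DataFrame:
    """Score every trial against the model for its landmark set.

    ``subjects`` must carry subject_id, group and sex. Returns the long-form
    K-Score table (one row per subject x repetition x landmark set). Subjects
    missing one of the expected repetitions are kept with the repetitions
    they have; the gap is logged, not raised.
    """
    info = subjects.set_index("subject_id")[["group", "sex"]]
    rows = []
    for trial in trials:
        name = trial.landmark_set.name
        if name not in models:
            raise ParameterError(f"no model supplied for landmark set {name!r}")
        meta = info.loc[trial.subject_id]
        rows.append(dict(
            subject_id=trial.subject_id,
            group=meta["group"],
            sex=meta["sex"],
            repetition_index=trial.repetition_index,
            landmark_set=name,
            kscore=score_trial(trial, models[name], allow_scaling=allow_scaling),
        ))
    table = pd.DataFrame.from_records(rows).sort_values(
        ["subject_id", "landmark_set", "repetition_index"], ignore_index=True
    )
    counts = table.groupby(["subject_id", "landmark_set"])["repetition_index"].count()
    for (sid, name), cnt in counts.items():
        if cnt < len(EXPECTED_REPETITIONS):
            logger.warning(
                "subject %s / %s: only %d of %d repetitions scored",
                sid, name, cnt, len(EXPECTED_REPETITIONS),
            )
    return table


def fit_all_references(
    trials_by_set: Mapping[str, Sequence[NormalizedTrial]],
    variance_threshold: float = 0.90,
    beta: float = 25.0,
    deviation_norm: str = "l1",
    allow_scaling: bool = False,
) -> dict[str, ReferenceModel]:
    """Fit independent reference models for each landmark set.

    Trunk and lower-extremity models are separate fits on their landmark
    subsets, not slices of the full-body model.
    """
    models = {}
    for name, trials in trials_by_set.items():
        get_landmark_set(name)  # validates the key
        models[name] = fit_reference(
            trials,
            variance_threshold=variance_threshold,
            beta=beta,
            deviation_norm=deviation_norm,
            allow_scaling=allow_scaling,
        )
    return models
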