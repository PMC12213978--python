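"""Seeded synthetic sit-to-stand cohorts: motion, impairment, covariates.

The generator produces 30 Hz landmark trajectories of repeated
seated-standing-seated cycles plus a pseudo-clinical covariate table, with
the statistical structure the downstream analysis assumes:

* kinematic primitives are closed-form (logistic vertical rise, cosine trunk
  flexion-extension arc, smooth deviation bumps), not a biomechanical forward
  model — the pipeline needs controllable, segment-specific deviation
  structure, not physiological fidelity;
* patient impairment is a per-subject deviation gain applied to trunk and/or
  lower-extremity landmarks, with male trunk gains larger than female trunk
  gains and identical lower-extremity gains across sexes;
* pressure pain thresholds are lognormal per group/sex/site with an
  instrument ceiling of 1500 kPa, and in males a Gaussian copula links the
  latent pain-site threshold to the trunk deviation gain (higher threshold,
  higher gain) while females are uncoupled;
* every draw is reproducible from (config, seed); each subject gets an
  independent spawned random stream.

Each synthetic session records its ground-truth repetition schedule
(threshold-crossing onset/offset frames of the noise-free spine_base vertical
velocity, and any scripted pause frames) in ``LandmarkTrajectory.meta`` — the
oracle used to validate segmentation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError
from .landmarks import LANDMARKS
from .mocap_io import LandmarkTrajectory

_LM = {name: i for i, name in enumerate(LANDMARKS)}

#: Impairment acts through two tied channels per body segment: a coordination
#: deviation (a progress-dependent phase lead/lag of the segment's rise, in
#: fractions of the transition per unit gain — up to ~0.2 s at typical
#: patient gains) and a proportional mediolateral sway pattern (meters per
#: unit gain). Both are driven by one subject-specific temporal mixture of
#: two shapes that vanish at the transition endpoints and are weighted to
#: have equal leverage on the scored profile, so the deviation *magnitude* is
#: carried by the gain while only its shape varies between subjects.
TRUNK_PHASE_SCALE = 0.16
LE_PHASE_SCALE = 0.135
TRUNK_SWAY_SCALE = 0.064
LE_SWAY_SCALE = 0.054
#: relative leverage weight of the sin(pi p) shape vs the sin(3 pi p) shape
SHAPE_BALANCE = 1.0

#: default segmentation-compatible velocity threshold used only to define the
#: scripted onset/offset oracle frames stored in session metadata.
_ORACLE_VELOCITY_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class MotionTemplate:
    """Closed-form sit-to-stand motion primitives for one subject.

    seat_height defaults to 0.432 m (a standard 17-inch chair). The rise and
    descent interpolate each landmark between a seated and a standing pose
    with a normalized logistic of steepness ``transition_duration / 12``;
    trunk flexion is a cosine arc peaking mid-transition, projected onto the
    landmarks above the spine base.
    """

    seat_height: float = 0.432
    stature: float = 1.70
    transition_duration: float = 1.3
    descent_duration: float = 1.3
    trunk_flexion_peak: float = 40.0  # degrees
    sit_dwell: float = 1.2
    stand_dwell: float = 1.1
    phase_offsets: dict = field(default_factory=dict)  # per-landmark, progress units

    def __post_init__(self):
        for name, value in (
            ("seat_height", self.seat_height),
            ("stature", self.stature),
            ("transition_duration", self.transition_duration),
            ("descent_duration", self.descent_duration),
            ("sit_dwell", self.sit_dwell),
            ("stand_dwell", self.stand_dwell),
        ):
            if value <= 0:
                raise ParameterError(f"{name} must be positive, got {value}")

    def poses(self) -> tuple[np.ndarray, np.ndarray]:
        """(seated, standing) 11 x 3 poses in meters; X ML, Y up, Z AP."""
        h = self.stature
        w = h / 1.70  # width scale
        s = self.seat_height
        standing = np.zeros((11, 3))
        seated = np.zeros((11, 3))

        def put(pose, name, x, y, z):
            pose[_LM[name]] = (x, y, z)

        for pose in (standing, seated):
            put(pose, "ankle_l", -0.11 * w, 0.04 * h, 0.0)
            put(pose, "ankle_r", +0.11 * w, 0.04 * h, 0.0)
        put(standing, "knee_l", -0.11 * w, 0.285 * h, 0.0)
        put(standing, "knee_r", +0.11 * w, 0.285 * h, 0.0)
        put(standing, "hip_l", -0.11 * w, 0.530 * h, 0.0)
        put(standing, "hip_r", +0.11 * w, 0.530 * h, 0.0)
        put(standing, "spine_base", 0.0, 0.570 * h, -0.02)
        put(standing, "spine_mid", 0.0, 0.700 * h, -0.02)
        put(standing, "shoulder_l", -0.18 * w, 0.820 * h, 0.0)
        put(standing, "shoulder_r", +0.18 * w, 0.820 * h, 0.0)
        put(standing, "neck", 0.0, 0.870 * h, 0.0)

        back = -0.42 * w  # seated pelvis/trunk sit behind the planted feet
        put(seated, "knee_l", -0.11 * w, 0.285 * h, 0.03)
        put(seated, "knee_r", +0.11 * w, 0.285 * h, 0.03)
        put(seated, "hip_l", -0.11 * w, s + 0.03, back + 0.02)
        put(seated, "hip_r", +0.11 * w, s + 0.03, back + 0.02)
        put(seated, "spine_base", 0.0, s + 0.10, back)
        put(seated, "spine_mid", 0.0, s + 0.10 + 0.13 * h, back)
        put(seated, "shoulder_l", -0.18 * w, s + 0.10 + 0.25 * h, back)
        put(seated, "shoulder_r", +0.18 * w, s + 0.10 + 0.25 * h, back)
        put(seated, "neck", 0.0, s + 0.10 + 0.30 * h, back)

        supra_knee = [
            _LM[n] for n in
            ("neck", "shoulder_l", "shoulder_r", "spine_mid", "spine_base",
             "hip_l", "hip_r")
        ]
        if np.any(standing[supra_knee, 1] <= seated[supra_knee, 1]):
            raise ParameterError(
                "invalid template geometry: standing pose not above seated pose"
            )
        return seated, standing


@dataclass
class ImpairmentParams:
    """Per-subject impairment controls.

    Gains of 0 reproduce the template up to sensor noise. ``trunk_deviation_gain``
    scales departures of the upper-trunk landmarks from the template (the
    spine base itself stays on-template so vertical-rise detection remains a
    property of the task, not the impairment); ``le_deviation_gain`` does the
    same for knees and hips.
    """

    trunk_deviation_gain: float = 0.0
    le_deviation_gain: float = 0.0
    timing_jitter_sd: float = 0.05   # seconds, on dwell durations
    pause_probability: float = 0.0   # per repetition
    within_subject_sd: float = 0.12  # lognormal sd of per-rep gain multiplier

    def __post_init__(self):
        if self.trunk_deviation_gain < 0 or self.le_deviation_gain < 0:
            raise ParameterError("deviation gains must be >= 0")
        if not 0.0 <= self.pause_probability <= 1.0:
            raise ParameterError("pause_probability must lie in [0, 1]")


@dataclass
class GroupDistributions:
    """Group/sex-specific sampling distributions (see CohortConfig)."""

    age_mean: float
    age_sd: float
    trunk_gain_mean: float
    trunk_gain_sd: float
    le_gain_mean: float
    le_gain_sd: float


@dataclass
class CohortConfig:
    """Study-condition defaults for the synthetic cohort.

    Counts and covariate targets mirror the emulated study: 62 pain-free
    controls (32% male), 110 female and 84 male chronic low-back-pain
    patients; PPT medians/spreads per group, sex and site; PASS-20 on
    [0, 100] and PROMIS-PI on [4, 20]; a male-only positive copula between
    latent pain-site PPT and trunk deviation gain.
    """

    n_ctrl: int = 62
    n_lbp_f: int = 110
    n_lbp_m: int = 84
    ctrl_male_fraction: float = 0.32
    n_reps: int = 5
    sample_rate: float = 30.0
    sensor_noise_sd: float = 0.001  # meters
    seat_height: float = 0.432
    pause_probability: float = 0.05
    timing_jitter_sd: float = 0.05
    within_subject_sd: float = 0.12
    rho_m: float = 0.75  # male latent pain-site PPT <-> trunk gain
    rho_f: float = 0.0
    ppt_ceiling: float = 1500.0
    ppt_reading_log_sd: float = 0.08
    seed: int = 12345

    # (group, sex) -> age / impairment-gain distributions
    groups: dict = field(default_factory=lambda: {
        ("CTRL", "F"): GroupDistributions(58, 21, 0.000, 0.015, 0.000, 0.010),
        ("CTRL", "M"): GroupDistributions(58, 21, 0.000, 0.015, 0.000, 0.010),
        ("LBP", "F"): GroupDistributions(55, 15, 0.420, 0.120, 0.380, 0.100),
        ("LBP", "M"): GroupDistributions(56, 16, 0.600, 0.120, 0.380, 0.100),
    })
    #: (group, sex, site) -> (median kPa, lognormal sigma)
    ppt: dict = field(default_factory=lambda: {
        ("LBP", "F", "control"): (295.0, 0.299),
        ("LBP", "F", "pain"): (291.0, 0.586),
        ("LBP", "M", "control"): (418.0, 0.517),
        ("LBP", "M", "pain"): (497.0, 0.628),
        ("CTRL", "F", "control"): (473.0, 0.437),
        ("CTRL", "M", "control"): (580.0, 0.568),
        ("CTRL", "F", "pain"): (550.0, 0.522),
        ("CTRL", "M", "pain"): (700.0, 0.459),
    })
    #: sex -> Beta(a, b); PASS-20 = 100*B, PROMIS-PI = 4 + 16*B
    pass20_beta: dict = field(default_factory=lambda: {
        "F": (3.2, 5.2), "M": (6.0, 10.0),
    })
    promis_beta: dict = field(default_factory=lambda: {
        "F": (1.3, 1.9), "M": (1.8, 2.9),
    })
    bmi_mean: float = 27.0
    bmi_sd: float = 4.0
    # Sex-neutral by design: the generator encodes no sex effect other than
    # the trunk-gain means and the PPT couplings, so score contrasts identify
    # impairment structure rather than body size.
    stature: dict = field(default_factory=lambda: {
        "F": (1.68, 0.008), "M": (1.68, 0.008),
    })
    trunk_flexion_mean: float = 40.0
    trunk_flexion_sd: float = 2.0
    duration_mean: float = 1.3
    duration_sd: float = 0.06

    def __post_init__(self):
        if min(self.n_ctrl, self.n_lbp_f, self.n_lbp_m) < 0:
            raise ParameterError("cohort counts must be >= 0")
        if self.ppt_ceiling <= 0:
            raise ParameterError("ppt_ceiling must be positive")


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _logistic_progress(p: np.ndarray, steepness: float = 1.0 / 12.0) -> np.ndarray:
    """Logistic in progress units, renormalized to hit exactly 0 and 1."""
    lo = 1.0 / (1.0 + np.exp(0.5 / steepness))
    hi = 1.0 / (1.0 + np.exp(-0.5 / steepness))
    s = 1.0 / (1.0 + np.exp(-(p - 0.5) / steepness))
    return (s - lo) / (hi - lo)


def _truncnorm(rng, mean, sd, lo, hi):
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def generate_session(
    template: MotionTemplate,
    impair: ImpairmentParams,
    n_reps: int = 5,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
    *,
    sample_rate: float = 30.0,
    noise_sd: float = 0.001,
    subject_id: str = "synthetic",
    group: str = "CTRL",
    sex: str = "F",
) -> LandmarkTrajectory:
    """Synthesize one n-repetition sit-to-stand session at 30 Hz.

    Deterministic given the seed. The returned trajectory's ``meta["reps"]``
    holds the scripted schedule: per repetition the onset/offset frames where
    the noise-free spine_base vertical velocity crosses the detection
    threshold, the wall-clock rise window, and any scripted pause frames.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    seated, standing = template.poses()
    dt = 1.0 / sample_rate

    # --- schedule ----------------------------------------------------------
    segments = []  # per rep: dict of wall-clock times
    t_cursor = max(0.3, template.sit_dwell + rng.normal(0.0, impair.timing_jitter_sd))
    rep_multipliers = np.exp(
        rng.normal(0.0, impair.within_subject_sd, size=n_reps)
    )
    for r in range(n_reps):
        pause_dur = 0.0
        if rng.random() < impair.pause_probability:
            pause_dur = rng.uniform(0.55, 0.85)
        rise_start = t_cursor
        pause_start = rise_start + 0.5 * template.transition_duration
        rise_end = rise_start + template.transition_duration + pause_dur
        stand_end = rise_end + max(
            0.3, template.stand_dwell + rng.normal(0.0, impair.timing_jitter_sd)
        )
        desc_end = stand_end + template.descent_duration
        segments.append(dict(
            rise_start=rise_start, pause_start=pause_start,
            pause_dur=pause_dur, rise_end=rise_end,
            stand_end=stand_end, desc_end=desc_end,
        ))
        t_cursor = desc_end + max(
            0.3, template.sit_dwell + rng.normal(0.0, impair.timing_jitter_sd)
        )
    total = segments[-1]["desc_end"] + template.sit_dwell
    t = np.arange(0.0, total, dt)
    n = t.size

    # --- progress curve and per-frame effective gains ----------------------
    prog = np.zeros(n)
    g_trunk = np.zeros(n)
    g_le = np.zeros(n)
    for r, seg in enumerate(segments):
        rise = (t >= seg["rise_start"]) & (t < seg["rise_end"])
        u = t[rise] - seg["rise_start"]
        if seg["pause_dur"] > 0:
            tp0 = seg["pause_start"] - seg["rise_start"]
            u = np.where(
                u >= tp0 + seg["pause_dur"], u - seg["pause_dur"],
                np.minimum(u, tp0),
            )
        prog[rise] = np.clip(u / template.transition_duration, 0.0, 1.0)
        stand = (t >= seg["rise_end"]) & (t < seg["stand_end"])
        prog[stand] = 1.0
        desc = (t >= seg["stand_end"]) & (t < seg["desc_end"])
        prog[desc] = np.clip(
            1.0 - (t[desc] - seg["stand_end"]) / template.descent_duration, 0.0, 1.0
        )
        active = (t >= seg["rise_start"]) & (t < seg["desc_end"])
        g_trunk[active] = impair.trunk_deviation_gain * rep_multipliers[r]
        g_le[active] = impair.le_deviation_gain * rep_multipliers[r]

    # --- clean kinematics + coordination deviations -------------------------
    # One unit temporal-mixture direction per segment; both mixture shapes
    # vanish at the transition endpoints and carry near-equal leverage on the
    # scored profile, so the gain alone sets the departure magnitude.
    c = rng.normal(0.0, 1.0, size=4)
    c[:2] /= np.linalg.norm(c[:2])
    c[2:] /= np.linalg.norm(c[2:])
    u1 = np.sin(np.pi * prog)
    u2 = np.sin(3.0 * np.pi * prog)
    mix_trunk = c[0] * SHAPE_BALANCE * u1 + c[1] * u2
    mix_le = c[2] * SHAPE_BALANCE * u1 + c[3] * u2

    offsets = np.array([
        template.phase_offsets.get(name, 0.0) for name in LANDMARKS
    ])
    # phase warp: the impaired segment leads/lags the template rise; the
    # spine base stays on-template (its vertical rise is the task itself)
    warp = np.zeros((prog.size, len(LANDMARKS)))
    for name in ("neck", "shoulder_l", "shoulder_r", "spine_mid"):
        warp[:, _LM[name]] = g_trunk * TRUNK_PHASE_SCALE * mix_trunk
    for name in ("hip_l", "hip_r", "knee_l", "knee_r"):
        warp[:, _LM[name]] = g_le * LE_PHASE_SCALE * mix_le
    p_lm = np.clip(prog[:, None] + warp - offsets[None, :], 0.0, 1.0)
    S_lm = _logistic_progress(p_lm)
    pos = seated[None] + (standing - seated)[None] * S_lm[:, :, None]

    # trunk flexion-extension arc about the spine base
    theta = np.deg2rad(template.trunk_flexion_peak) * np.sin(np.pi * prog)
    base_y = seated[_LM["spine_base"], 1]
    for name in ("spine_mid", "shoulder_l", "shoulder_r", "neck"):
        i = _LM[name]
        lever = seated[i, 1] - base_y
        pos[:, i, 2] += lever * np.sin(theta)
        pos[:, i, 1] -= lever * (1.0 - np.cos(theta))

    # --- tied mediolateral sway patterns ------------------------------------
    sway = g_trunk * TRUNK_SWAY_SCALE * mix_trunk
    pos[:, _LM["shoulder_l"], 0] += sway
    pos[:, _LM["shoulder_r"], 0] -= sway
    pos[:, _LM["neck"], 0] += 0.5 * sway

    le_ml = g_le * LE_SWAY_SCALE * mix_le
    pos[:, _LM["knee_l"], 0] += le_ml
    pos[:, _LM["knee_r"], 0] -= le_ml

    # --- oracle schedule from the noise-free vertical signal ----------------
    clean_base_y = pos[:, _LM["spine_base"], 1].copy()
    v_clean = np.gradient(clean_base_y, t)
    reps_meta = []
    for r, seg in enumerate(segments):
        lo = int(np.searchsorted(t, seg["rise_start"]))
        hi = int(np.searchsorted(t, seg["rise_end"]))
        window = np.arange(lo, hi)
        crossing = window[v_clean[lo:hi] > _ORACLE_VELOCITY_THRESHOLD]
        pause_frames: list[int] = []
        if seg["pause_dur"] > 0:
            pause_frames = np.flatnonzero(
                (t >= seg["pause_start"])
                & (t < seg["pause_start"] + seg["pause_dur"])
            ).tolist()
        reps_meta.append(dict(
            index=r + 1,
            onset_frame=int(crossing[0]),
            offset_frame=int(crossing[-1]),
            rise_window=[lo, hi],
            pause_frames=pause_frames,
        ))

    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, size=pos.shape)

    return LandmarkTrajectory(
        subject_id=subject_id,
        group=group,
        sex=sex,
        sample_rate=sample_rate,
        timestamps=t,
        positions=pos,
        meta={
            "reps": reps_meta,
            "impairment": asdict(impair),
            "template": {
                "stature": template.stature,
                "transition_duration": template.transition_duration,
                "trunk_flexion_peak": template.trunk_flexion_peak,
            },
            "shape_coefs": c.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# Cohort synthesis
# ---------------------------------------------------------------------------

def _draw_subject(cfg: CohortConfig, group: str, sex: str, rng) -> dict:
    """Draw one subject's latent parameters (no motion)."""
    dist = cfg.groups[(group, sex)]
    z_gain = rng.normal()
    trunk_gain = max(0.0, dist.trunk_gain_mean + dist.trunk_gain_sd * z_gain)
    if group == "CTRL":
        trunk_gain = min(trunk_gain, 0.045)  # manifest invariant: CTRL < 0.05
    le_gain = max(0.0, rng.normal(dist.le_gain_mean, dist.le_gain_sd))
    if group == "CTRL":
        le_gain = min(le_gain, 0.045)

    rho = {"M": cfg.rho_m, "F": cfg.rho_f}[sex] if group == "LBP" else 0.0
    z_pain = rho * z_gain + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal()
    med_pain, sd_pain = cfg.ppt[(group, sex, "pain")]
    med_ctrl, sd_ctrl = cfg.ppt[(group, sex, "control")]
    ppt_pain_latent = min(cfg.ppt_ceiling, med_pain * np.exp(sd_pain * z_pain))
    ppt_ctrl_latent = min(
        cfg.ppt_ceiling, med_ctrl * np.exp(sd_ctrl * rng.normal())
    )
    readings = {
        site: np.minimum(
            cfg.ppt_ceiling,
            latent * np.exp(rng.normal(0.0, cfg.ppt_reading_log_sd, size=3)),
        ).tolist()
        for site, latent in (
            ("control", ppt_ctrl_latent), ("pain", ppt_pain_latent),
        )
    }
    a, b = cfg.pass20_beta[sex]
    pass20 = 100.0 * rng.beta(a, b)
    a, b = cfg.promis_beta[sex]
    promis = 4.0 + 16.0 * rng.beta(a, b)

    mu_h, sd_h = cfg.stature[sex]
    return dict(
        group=group,
        sex=sex,
        age_years=_truncnorm(rng, dist.age_mean, dist.age_sd, 21.0, 85.0),
        bmi=_truncnorm(rng, cfg.bmi_mean, cfg.bmi_sd, 18.0, 35.0),
        stature=_truncnorm(rng, mu_h, sd_h, 1.40, 2.05),
        trunk_flexion_peak=rng.normal(cfg.trunk_flexion_mean, cfg.trunk_flexion_sd),
        transition_duration=max(0.9, rng.normal(cfg.duration_mean, cfg.duration_sd)),
        trunk_gain=float(trunk_gain),
        le_gain=float(le_gain),
        ppt_pain_latent=float(ppt_pain_latent),
        ppt_control_latent=float(ppt_ctrl_latent),
        ppt_readings=readings,
        pass20=float(pass20),
        promis_pi=float(promis),
    )


def generate_cohort(
    config: CohortConfig | None = None, *, motion: bool = True
) -> tuple[list[LandmarkTrajectory], pd.DataFrame, dict]:
    """Generate the full synthetic cohort.

    Returns (trajectories, covariate table, manifest). With ``motion=False``
    the trajectory list is empty but all latent draws — and hence the
    manifest and covariates — are identical, which makes large
    covariate-only Monte Carlo draws cheap.
    """
    cfg = config or CohortConfig()
    root = np.random.SeedSequence(cfg.seed)
    roster: list[tuple[str, str]] = []
    sex_rng = np.random.default_rng(root.spawn(1)[0])
    for _ in range(cfg.n_ctrl):
        roster.append(("CTRL", "M" if sex_rng.random() < cfg.ctrl_male_fraction else "F"))
    roster += [("LBP", "F")] * cfg.n_lbp_f + [("LBP", "M")] * cfg.n_lbp_m

    child_seeds = root.spawn(len(roster))
    trajectories: list[LandmarkTrajectory] = []
    records = []
    subjects_manifest = []
    for i, ((group, sex), ss) in enumerate(zip(roster, child_seeds)):
        rng = np.random.default_rng(ss)
        sid = f"S{i:04d}"
        lat = _draw_subject(cfg, group, sex, rng)
        rep_schedule = None
        if motion:
            template = MotionTemplate(
                seat_height=cfg.seat_height,
                stature=lat["stature"],
                transition_duration=lat["transition_duration"],
                trunk_flexion_peak=lat["trunk_flexion_peak"],
            )
            impair = ImpairmentParams(
                trunk_deviation_gain=lat["trunk_gain"],
                le_deviation_gain=lat["le_gain"],
                timing_jitter_sd=cfg.timing_jitter_sd,
                pause_probability=cfg.pause_probability,
                within_subject_sd=cfg.within_subject_sd,
            )
            traj = generate_session(
                template, impair, n_reps=cfg.n_reps, seed=rng,
                sample_rate=cfg.sample_rate, noise_sd=cfg.sensor_noise_sd,
                subject_id=sid, group=group, sex=sex,
            )
            trajectories.append(traj)
            rep_schedule = traj.meta["reps"]
        rc, rp = lat["ppt_readings"]["control"], lat["ppt_readings"]["pain"]
        records.append(dict(
            subject_id=sid, group=group, sex=sex,
            age_years=lat["age_years"], bmi=lat["bmi"],
            pass20=lat["pass20"], promis_pi=lat["promis_pi"],
            ppt_control_1_kpa=rc[0], ppt_control_2_kpa=rc[1],
            ppt_control_3_kpa=rc[2],
            ppt_pain_1_kpa=rp[0], ppt_pain_2_kpa=rp[1], ppt_pain_3_kpa=rp[2],
        ))
        subjects_manifest.append(dict(
            subject_id=sid,
            group=group,
            sex=sex,
            trunk_gain=lat["trunk_gain"],
            le_gain=lat["le_gain"],
            ppt_pain_latent=lat["ppt_pain_latent"],
            ppt_control_latent=lat["ppt_control_latent"],
            stature=lat["stature"],
            transition_duration=lat["transition_duration"],
            trunk_flexion_peak=lat["trunk_flexion_peak"],
            rep_schedule=rep_schedule,
        ))
    covariates = pd.DataFrame.from_records(records)
    manifest = cohort_manifest(cfg, subjects_manifest)
    return trajectories, covariates, manifest


def cohort_manifest(config: CohortConfig, subjects: list[dict] | None = None) -> dict:
    """Provenance record: config + seed + per-subject latent parameters."""
    cfg_dict = asdict(config)
    cfg_dict["groups"] = {
        "|".join(k): asdict(v) for k, v in config.groups.items()
    }
    cfg_dict["ppt"] = {"|".join(k): list(v) for k, v in config.ppt.items()}
    for key in ("pass20_beta", "promis_beta", "stature"):
        cfg_dict[key] = {k: list(v) for k, v in cfg_dict[key].items()}
    return {
        "format": "kscore-cohort-manifest v1",
        "seed": config.seed,
        "config": cfg_dict,
        "subjects": subjects if subjects is not None else [],
    }


def manifest_to_config(manifest: dict) -> CohortConfig:
    """Rebuild a CohortConfig from a manifest (inverse of cohort_manifest)."""
    cfg_dict = dict(manifest["config"])
    cfg_dict["groups"] = {
        tuple(k.split("|")): GroupDistributions(**v)
        for k, v in cfg_dict["groups"].items()
    }
    cfg_dict["ppt"] = {
        tuple(k.split("|")): tuple(v) for k, v in cfg_dict["ppt"].items()
    }
    for key in ("pass20_beta", "promis_beta", "stature"):
        cfg_dict[key] = {k: tuple(v) for k, v in cfg_dict[key].items()}
    return CohortConfig(**cfg_dict)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
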