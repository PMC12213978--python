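# Methods

## Scope and data model

The package scores movement quality of sit-to-stand (STS) transitions from
3D landmark trajectories and runs the group statistics such scores feed. A
subject-session is a 30 Hz time series of 11 landmarks — neck, left/right
shoulders, mid-spine, spine base (trunk); left/right hips, knees, ankles
(lower extremities) — in meters, with X mediolateral, Y vertical (up
positive), Z anteroposterior. Sessions travel in a comma-delimited text
dialect (one metadata comment line, one header row, one row per frame per
session block); runs of up to 5 consecutive missing frames per coordinate
are linearly interpolated on read, longer gaps are rejected.

## Segmentation

The STS transition is defined as the motion from seated to standing,
excluding pauses. Detection thresholds the smoothed upward vertical velocity
of the spine base, the most proximal trunk landmark to the seat:

| parameter | default | meaning |
|---|---|---|
| `velocity_threshold_ms` | 0.05 m/s | onset/offset crossing level |
| `smoothing_window` | 5 frames | moving average on the velocity |
| `min_duration_s` | 0.5 s | shorter supra-threshold runs are noise |
| `max_pause_gap_s` | 0.3 s | longer interior plateaus are excised |
| `max_merge_gap_s` | 3.0 s | descent-free gap still counted as one rise |
| `min_displacement_m` | 0.10 m | minimum net vertical rise |
| `min_run_frames` | 2 | debounce against single-frame chatter |

A repetition spans the first to the last threshold crossing of one rise;
supra-threshold runs separated by a gap containing no descent (no sustained
velocity below −threshold) are one paused repetition. Excised pauses are
*collapsed to motion time* — the body is stationary during a pause, so the
transition resumes where it stopped; without this collapse a paused trial's
normalized profile is badly distorted by the pause's wall time. The first
repetition is dropped (greater variability); repetitions keep their original
numbering 2–5. Each transition is then min–max mapped onto [0, 1] in time
and resampled to a uniform grid (101 points, the 0–100% convention;
configurable). Amplitude is deliberately not min–max scaled: amplitude
standardization is the alignment step's job, and an optional Procrustes
scaling flag exists for sensitivity analysis (off by default).

## Reference model and scores

The reference is fit on control trials only; patients are projected into the
control space, which keeps scores consistent when patient data is added.
All control time points are stacked (each row one time point's flattened
coordinates), centered, and decomposed by PCA; the minimal k with cumulative
explained variance ≥ `variance_threshold` (default 0.90) is retained, ties
broken by component order. Component signs follow a deterministic
convention (largest-magnitude loading positive) so weighted sums are
reproducible across linear-algebra backends. Each trial's T×k PC trajectory
is superimposed on the control-average PC trajectory by ordinary Procrustes
analysis — translation and rotation; because the reference is a fixed
control average, no iterative generalized alignment is needed. The
K-Profile is the per-time-point sum of aligned PC scores weighted by the
retained explained-variance ratios renormalized to sum to one ("most
prominent patterns" weighting). The deviation D is the mean absolute
profile difference from the control average (mean, not sum, so the score is
grid-size invariant; an L2 option exists), and

    K = 100 · (1 − D / (β · D_cal)),   D_cal = mean control-trial deviation.

The anchor at 100 is exact by construction; scores are unbounded below and
never clipped. β (default 25) sets how far one control-average deviation
unit falls below 100: with β = 25 the average control trial scores 96 and
the synthetic patient groups land in the 70s–80s, the range published
score tables occupy. β and D_cal are serialized with the model; no
acceptance quantity depends on β. Trunk and lower-extremity models are
independent fits on their landmark subsets — slicing a full-body PC space
would entangle the segments.

## Synthetic cohort

The generator emulates the study conditions: 62 pain-free controls (32%
male) and 110 female / 84 male LBP patients, each performing five STS
repetitions at 30 Hz from a 17-inch (0.432 m) chair. Kinematics are
closed-form primitives — a normalized logistic rise between a seated and a
standing pose (steepness duration/12), a cosine trunk flexion–extension arc
(40° ± 2° peak), dwell phases, and stand-to-sit descents — not a
biomechanical forward model; the pipeline needs controllable,
segment-specific deviation structure, not physiological fidelity.

Impairment is a per-subject, per-segment deviation gain acting through two
tied channels: a coordination deviation (the impaired segment's landmarks
lead/lag the template rise by up to ~0.2 s at typical gains) and a
proportional mediolateral sway pattern. Both are driven by one
subject-specific temporal mixture of sin(πt) and sin(3πt) — shapes that
vanish at the transition endpoints and carry near-equal leverage on the
scored profile, so the *magnitude* of a subject's departure is set by the
gain while only its shape varies. The spine base itself stays on-template:
its vertical rise is the task, and keeping it clean makes the generator's
scripted onset/offset schedule (stored in session metadata, computed from
the noise-free vertical velocity) a valid segmentation oracle. Within-
subject repetition variability is a multiplicative lognormal jitter on the
gains (σ = 0.12); sessions carry 1 mm Gaussian sensor noise (smoothed
landmark-tracking jitter); pauses are inserted mid-rise with probability
0.05 per repetition and their frame schedule recorded.

Configured truths, chosen to mirror the emulated study's effect structure:
male trunk gains exceed female trunk gains (0.60 ± 0.12 vs 0.42 ± 0.12,
controls ≈ 0), lower-extremity gains are sex-neutral (0.38 ± 0.10 in both
LBP groups), and in males only a Gaussian copula (ρ = 0.75) links the
latent pain-site pressure-pain threshold to the trunk gain — higher
threshold, higher gain — producing the negative PPT→tK-Score association
without distorting the marginals. Pain measures are lognormal per
group/sex/site (medians 295/418 kPa control site and 291/497 kPa pain site
for LBP-F/LBP-M; spreads matched to published interquartile ranges via
σ = asinh(IQR/2m)/z₀.₇₅), truncated at the 1500 kPa instrument ceiling,
with three readings per site (log-SD 0.08) averaged downstream. PASS-20 and
PROMIS-PI are scaled Beta distributions on [0, 100] and [4, 20] with
sex-wise medians near the published values and no sex effect.

What the generator does **not** emulate: sex-specific anthropometry
(stature is sex-neutral by design so that score contrasts identify
impairment structure rather than body size), depth-sensor artifacts
(occlusion, landmark swaps), LBP etiology, and any distributional shape
information beyond the published medians/IQRs and means/SDs — individual-
level distributions are unconstrained by the emulation targets. Passing
tests therefore show that the *pipeline* recovers structure it is known to
contain, not that real capture data is this clean.

## Statistics

* **PPT aggregation**: arithmetic mean of the three readings per site;
  readings above 1500 kPa or non-positive are range errors.
* **Normality screen**: Shapiro–Wilk, used to gate and report the rank-based
  path.
* **Rank ANCOVA** (Conover-style): outcome rank-transformed (average ranks
  on ties), OLS on group + age + BMI, group-coefficient t-test; optional
  permutation p; groups reported as median ± IQR.
* **Mixed model**: K-Score ~ group × repetition (saturated means model) with
  a per-subject random intercept and group-specific residual variances.
  Estimation is maximum likelihood — each subject's marginal covariance
  σ_b²J + σ_g²I has Sherman–Morrison closed forms, so the profile
  log-likelihood over the (log-parameterized) variance components is
  optimized directly (Nelder–Mead). ML rather than REML so the interaction
  test is a valid likelihood ratio across nested fixed-effect structures;
  the LRT statistic is referred to χ² with (G−1)(R−1) degrees of freedom.
  statsmodels' MixedLM reproduces the shared-variance special case and
  serves as the independent cross-check in the tests.
* **Contrast adjustment**: single-step max-|t| by default, computed from the
  contrasts' estimated correlation with a common-draw Monte Carlo reference
  distribution (2¹⁷ draws, fixed internal seed — deterministic, and common
  draws make adjusted p monotone in |t|). Bonferroni and Holm selectable;
  adjusted p is floored at raw p.
* **Regressions**: per-subject tK-Score averaged over repetitions 2–5 as
  outcome; the pain measure, age and BMI Spearman-rank transformed; one OLS
  per pain measure, optionally sex-stratified; R² classified weak/moderate/
  strong with boundary values (exactly 0.16 or 0.36) assigned to the lower
  category, since the published cutoffs are strict inequalities.

## Numerical choices and degenerate inputs

Gap interpolation is linear and refuses edge gaps. Zero-variance vertical
signals, constant samples, rank-deficient all-zero control stacks, and
missing calibration raise typed errors rather than propagating NaNs. The
deviation calibration D_cal must be strictly positive; numerically identical
control trials are rejected. Procrustes rotations may include reflections
(standard orthogonal superimposition). Reader/writer round-trips are
lossless to 1e-9 (12 significant digits in the dialect).

## Problem sizes in the test and acceptance suites

The suites run the full default cohort (n = 256) once for effect-structure
recovery; segmentation fidelity uses 100 seeded sessions (500 transitions);
score-calibration nulls use 1,000 rank-ANCOVA replicates at n = 200 per
group and 100 zero-impairment cohorts of 42 subjects each; remaining unit
and property tests use cohorts of 5–34 subjects and toy 3-time-point
configurations against a hand-coded brute-force scorer. These sizes were
chosen so the whole suite completes in a few minutes while keeping every
statistical check at the replicate counts stated above.

## Known limitations

The zero-impairment score spread is dominated by segmentation boundary
jitter propagated through time normalization (trial deviation cv ≈ 0.6), so
individual zero-gain scores scatter several points around the control mean
even though group contrasts stay calibrated; interpretation of *individual*
synthetic scores should respect that floor. The mixed model's contrast
p-values use the normal reference (no small-sample degrees-of-freedom
correction), adequate at the cohort sizes used here. The leK-Score sex
contrast is a true null in the generator, so at any single seed the
family-adjusted test retains its nominal ~5% false-positive probability.
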