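"""Control-referenced scoring: PCA reference, Procrustes, K-Profile/K-Score."""

import numpy as np
import pytest

from kscore.landmarks import TRUNK
from kscore.mocap_io import NormalizedTrial
from kscore.scoring import (
    ReferenceModel,
    align_configuration,
    compute_kprofile,
    compute_kscore,
    fit_reference,
    project_and_align,
    score_cohort,
    score_trial,
)
from kscore.errors import DegenerateInputError, ParameterError
from oracle_reference import brute_force_model, brute_force_score


def toy_trial(coords, rep=2, sid="S"):
    coords = np.asarray(coords, dtype=float)
    return NormalizedTrial(
        subject_id=sid, repetition_index=rep, grid_size=coords.shape[0],
        normalized_time=np.linspace(0, 1, coords.shape[0]),
        coords=coords, landmark_set=TRUNK,
    )


def toy_controls(rng, n=6, t=3, d=6, scale=0.1):
    base = rng.normal(0.0, 1.0, size=(t, d))
    return [base + rng.normal(0.0, scale, size=(t, d)) for _ in range(n)]


class TestOracleEquivalence:
    """Full pipeline vs independent hand-coded brute force, to 1e-10."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_toy_pipeline_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        controls = toy_controls(rng)
        oracle = brute_force_model(controls, 0.90, beta=25.0)
        model = fit_reference([toy_trial(c) for c in controls], 0.90, beta=25.0)

        np.testing.assert_allclose(model.column_means, oracle["mu"], atol=1e-10)
        np.testing.assert_allclose(model.basis, oracle["basis"], atol=1e-10)
        np.testing.assert_allclose(model.weights, oracle["weights"], atol=1e-10)
        np.testing.assert_allclose(
            model.reference_profile, oracle["ref_profile"], atol=1e-10
        )
        assert model.d_cal == pytest.approx(oracle["d_cal"], abs=1e-10)

        for _ in range(5):
            probe = controls[0] + rng.normal(0, 0.3, size=controls[0].shape)
            assert score_trial(toy_trial(probe), model) == pytest.approx(
                brute_force_score(oracle, probe), abs=1e-10
            )


class TestFitReference:
    def test_full_threshold_retains_full_rank(self, rng):
        controls = toy_controls(rng, n=5)
        model = fit_reference([toy_trial(c) for c in controls], 1.0)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_small_noise_cohort_keeps_few_components(self, rng):
        # smooth rank-2 template: variance concentrates on two components
        grid = np.linspace(0, 1, 20)
        template = (
            np.outer(np.sin(np.pi * grid), rng.normal(size=15))
            + np.outer(grid, rng.normal(size=15))
        )
        controls = [
            toy_trial(template + rng.normal(0, 0.01, size=template.shape))
            for _ in range(8)
        ]
        model = fit_reference(controls, 0.90)
        assert model.n_components <= 5
        projected = (template - model.column_means) @ model.basis.T
        assert np.abs(model.reference_config - projected).max() < 0.05

    def test_duplicate_trials_weight_the_reference_mean(self, rng):
        a = rng.normal(size=(4, 6))
        b = a + rng.normal(0, 0.5, size=a.shape)
        model = fit_reference([toy_trial(a), toy_trial(a), toy_trial(b)], 1.0)
        pa = (a - model.column_means) @ model.basis.T
        pb = (b - model.column_means) @ model.basis.T
        np.testing.assert_allclose(
            model.reference_config, (2 * pa + pb) / 3, atol=1e-9
        )

    def test_orthonormal_basis(self, small_cohort):
        for model in small_cohort["models"].values():
            gram = model.basis @ model.basis.T
            np.testing.assert_allclose(gram, np.eye(model.n_components), atol=1e-8)

    def test_zero_variance_is_degenerate(self):
        flat = [toy_trial(np.ones((3, 6))) for _ in range(3)]
        with pytest.raises(DegenerateInputError):
            fit_reference(flat)

    def test_mixed_landmark_sets_rejected(self, rng):
        trials = [toy_trial(c) for c in toy_controls(rng, n=3)]
        trials[1].grid_size = 4
        trials[1].coords = rng.normal(size=(4, 6))
        with pytest.raises(ParameterError):
            fit_reference(trials)

    def test_json_round_trip(self, small_cohort, tmp_path):
        model = small_cohort["models"]["trunk"]
        path = tmp_path / "m.json"
        model.to_json(path)
        back = ReferenceModel.from_json(path)
        np.testing.assert_allclose(back.basis, model.basis)
        np.testing.assert_allclose(back.reference_profile, model.reference_profile)
        assert back.d_cal == model.d_cal and back.beta == model.beta


class TestProcrustes:
    def test_reference_aligns_to_itself(self, small_cohort):
        model = small_cohort["models"]["trunk"]
        aligned = align_configuration(model.reference_config, model.reference_config)
        np.testing.assert_allclose(aligned, model.reference_config, atol=1e-10)

    def test_similarity_transform_recovered_exactly(self, rng):
        ref = rng.normal(size=(10, 3))
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        moved = ref @ rot + np.array([0.5, -1.0, 2.0])
        aligned = align_configuration(moved, ref)
        assert np.linalg.norm(aligned - ref) < 1e-8

    def test_alignment_never_increases_distance(self, rng):
        ref = rng.normal(size=(8, 4))
        for _ in range(100):
            config = ref + rng.normal(0, rng.uniform(0.1, 2.0), size=ref.shape)
            pre = np.linalg.norm(config - ref)
            post = np.linalg.norm(align_configuration(config, ref) - ref)
            assert post <= pre + 1e-12


class TestKProfileAndScore:
    def test_reference_profile_is_its_own_kprofile(self, small_cohort):
        model = small_cohort["models"]["full_body"]
        profile = compute_kprofile(model.reference_config, model)
        np.testing.assert_allclose(profile.values, model.reference_profile, atol=1e-12)

    def test_hand_computed_two_component_profile(self):
        model = ReferenceModel(
            landmark_set="trunk", grid_size=3,
            column_means=np.zeros(6), basis=np.eye(6)[:2],
            weights=np.array([0.75, 0.25]),
            explained_variance_ratio=np.array([0.6, 0.2]),
            variance_threshold=0.8,
            reference_config=np.zeros((3, 2)),
            reference_profile=np.zeros(3),
            d_cal=1.0,
        )
        aligned = np.array([[1.0, 2.0], [3.0, -4.0], [0.0, 8.0]])
        profile = compute_kprofile(aligned, model)
        np.testing.assert_allclose(profile.values, [1.25, 1.25, 2.0])

    def test_anchor_scores_100_exactly(self, small_cohort):
        """The control-average trajectory itself scores exactly 100."""
        for model in small_cohort["models"].values():
            profile = compute_kprofile(model.reference_config, model)
            assert compute_kscore(profile, model) == 100.0

    def test_doubling_deviation_doubles_score_gap(self, small_cohort):
        model = small_cohort["models"]["trunk"]
        trial = small_cohort["trials_by_set"]["trunk"][5]
        aligned = project_and_align(trial, model)
        profile = compute_kprofile(aligned, model).values
        doubled = model.reference_profile + 2 * (profile - model.reference_profile)
        s1 = compute_kscore(profile, model)
        s2 = compute_kscore(doubled, model)
        assert 100.0 - s2 == pytest.approx(2 * (100.0 - s1), rel=1e-9)

    def test_monotone_degradation(self, small_cohort):
        model = small_cohort["models"]["trunk"]
        trial = small_cohort["trials_by_set"]["trunk"][40]
        aligned = project_and_align(trial, model)
        base = compute_kprofile(aligned, model).values
        lams = np.linspace(0.0, 4.0, 9)
        scores = [
            compute_kscore(
                model.reference_profile + lam * (base - model.reference_profile),
                model,
            )
            for lam in lams
        ]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_missing_calibration_is_state_error(self):
        from kscore.errors import ModelStateError
        model = ReferenceModel(
            landmark_set="trunk", grid_size=3, column_means=np.zeros(6),
            basis=np.eye(6)[:1], weights=np.ones(1),
            explained_variance_ratio=np.ones(1), variance_threshold=0.9,
            reference_config=np.zeros((3, 1)), reference_profile=np.zeros(3),
            d_cal=None,
        )
        with pytest.raises(ModelStateError):
            compute_kscore(np.zeros(3), model)


class TestCohortScoring:
    def test_row_count_is_twelve_per_subject(self, small_cohort):
        table = small_cohort["table"]
        n_subjects = small_cohort["covariates"].shape[0]
        assert len(table) == 12 * n_subjects
        assert set(table["repetition_index"]) == {2, 3, 4, 5}

    def test_trunk_only_perturbation_hits_trunk_score_hardest(self):
        from kscore.pipeline import (
            RunConfig, simulate_stage, normalize_stage, fit_stage, score_stage,
        )
        cfg = RunConfig(seed=31)
        cfg.cohort.n_ctrl, cfg.cohort.n_lbp_f, cfg.cohort.n_lbp_m = 8, 6, 0
        cfg.cohort.groups[("LBP", "F")].trunk_gain_mean = 0.6
        cfg.cohort.groups[("LBP", "F")].trunk_gain_sd = 0.05
        cfg.cohort.groups[("LBP", "F")].le_gain_mean = 0.0
        cfg.cohort.groups[("LBP", "F")].le_gain_sd = 0.0
        trajs, cov, _ = simulate_stage(cfg)
        trials = normalize_stage(cfg, trajs)
        models = fit_stage(cfg, trials, cov)
        table = score_stage(cfg, trials, models, cov)
        lbp = table[table["group"] == "LBP"]
        per_rep = lbp.pivot_table(
            index=["subject_id", "repetition_index"],
            columns="landmark_set", values="kscore",
        )
        assert (per_rep["trunk"] < per_rep["lower_extremity"]).all()

    def test_grid_invariance_of_scores(self):
        """Doubling the grid changes a smooth trial's score by < 0.5 points."""
        from kscore.pipeline import (
            RunConfig, simulate_stage, normalize_stage, fit_stage, score_stage,
        )
        scores = {}
        for grid in (101, 201):
            cfg = RunConfig(seed=17)
            cfg.grid_size = grid
            cfg.cohort.n_ctrl, cfg.cohort.n_lbp_f, cfg.cohort.n_lbp_m = 8, 4, 0
            trajs, cov, _ = simulate_stage(cfg)
            trials = normalize_stage(cfg, trajs)
            models = fit_stage(cfg, trials, cov)
            table = score_stage(cfg, trials, models, cov)
            scores[grid] = table.set_index(
                ["subject_id", "repetition_index", "landmark_set"]
            )["kscore"]
        diff = (scores[101] - scores[201]).abs()
        assert diff.max() < 0.5

    def test_rigid_motion_changes_score_by_less_than_one_point(self):
        """A global rotation+translation of the raw capture barely moves scores."""
        from kscore.pipeline import (
            RunConfig, simulate_stage, normalize_stage, fit_stage, score_stage,
        )
        cfg = RunConfig(seed=23)
        cfg.cohort.n_ctrl, cfg.cohort.n_lbp_f, cfg.cohort.n_lbp_m = 8, 3, 0
        trajs, cov, _ = simulate_stage(cfg)
        trials = normalize_stage(cfg, trajs)
        models = fit_stage(cfg, trials, cov)
        base = score_stage(cfg, trials, models, cov)

        theta = np.deg2rad(5.0)
        rot = np.array([
            [np.cos(theta), 0, np.sin(theta)],
            [0, 1, 0],
            [-np.sin(theta), 0, np.cos(theta)],
        ])
        target = trajs[-1]
        centroid = target.positions.mean(axis=(0, 1))
        target.positions = (target.positions - centroid) @ rot.T + centroid + 0.05
        moved_trials = normalize_stage(cfg, [target])
        moved = score_stage(cfg, moved_trials, models, cov)
        sid = target.subject_id
        merged = base[base.subject_id == sid].merge(
            moved, on=["subject_id", "repetition_index", "landmark_set"],
            suffixes=("_base", "_moved"),
        )
        assert len(merged) == 12
        assert (merged["kscore_base"] - merged["kscore_moved"]).abs().max() < 1.0
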