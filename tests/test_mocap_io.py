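"""Trajectory I/O, sit-to-stand segmentation and time normalization."""

import numpy as np
import pytest

from kscore.errors import (
    DataError,
    DegenerateInputError,
    ParameterError,
    SchemaError,
    SegmentationError,
)
from kscore.landmarks import COORD_COLUMNS, FULL_BODY, LANDMARKS, TRUNK
from kscore.mocap_io import (
    LandmarkTrajectory,
    STSRepetition,
    drop_first_repetition,
    read_trajectories,
    segment_sts,
    time_normalize,
    write_trajectories,
)
from kscore.simulate import ImpairmentParams, MotionTemplate, generate_session


def make_traj(n=30, subject_id="S1", rng=None):
    t = np.arange(n) / 30.0
    rng = rng or np.random.default_rng(0)
    pos = rng.normal(0.5, 0.2, size=(n, 11, 3))
    return LandmarkTrajectory(subject_id, "CTRL", "F", 30.0, t, pos)


# ---------------------------------------------------------------------------
# reader / writer
# ---------------------------------------------------------------------------

class TestFileRoundTrip:
    def test_two_subject_round_trip(self, tmp_path):
        trajs = [make_traj(subject_id="A"), make_traj(40, subject_id="B")]
        path = tmp_path / "t.csv"
        write_trajectories(trajs, path)
        back = read_trajectories(path)
        assert [b.subject_id for b in back] == ["A", "B"]
        for orig, new in zip(trajs, back):
            np.testing.assert_allclose(new.timestamps, orig.timestamps, atol=1e-9)
            np.testing.assert_allclose(new.positions, orig.positions, atol=1e-9)
            assert (new.group, new.sex, new.sample_rate) == ("CTRL", "F", 30.0)

    def test_empty_collection_gives_header_only_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_trajectories([], path)
        assert path.read_text().startswith("#")
        assert read_trajectories(path) == []

    def test_interior_gap_interpolated_exactly_on_ramp(self, tmp_path):
        traj = make_traj(20)
        # knee_l x-column follows a linear ramp, so interpolation is exact
        col = COORD_COLUMNS.index("knee_l_x")
        ramp = np.linspace(0.0, 1.0, 20)
        traj.positions[:, LANDMARKS.index("knee_l"), 0] = ramp
        path = tmp_path / "gap.csv"
        write_trajectories([traj], path)
        lines = path.read_text().splitlines()
        for frame in (7, 8, 9):  # 3-frame interior gap
            fields = lines[3 + frame].split(",")
            fields[1 + col] = ""
            lines[3 + frame] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        back = read_trajectories(path)[0]
        np.testing.assert_allclose(
            back.positions[:, LANDMARKS.index("knee_l"), 0], ramp, atol=1e-9
        )

    def test_long_gap_is_data_error_naming_frames(self, tmp_path):
        traj = make_traj(20)
        path = tmp_path / "gap.csv"
        write_trajectories([traj], path)
        lines = path.read_text().splitlines()
        col = COORD_COLUMNS.index("neck_y")
        for frame in range(5, 12):  # 7 missing frames > the 5-frame tolerance
            fields = lines[3 + frame].split(",")
            fields[1 + col] = ""
            lines[3 + frame] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DataError, match="neck_y.*5..11"):
            read_trajectories(path)

    def test_missing_landmark_columns_is_schema_error(self, tmp_path):
        traj = make_traj(5)
        path = tmp_path / "bad.csv"
        write_trajectories([traj], path)
        text = path.read_text()
        drop = [f"ankle_r_{ax}" for ax in "xyz"]
        lines = text.splitlines()
        header = lines[2].split(",")
        keep = [i for i, name in enumerate(header) if name not in drop]
        lines[2] = ",".join(header[i] for i in keep)
        for j in range(3, len(lines)):
            fields = lines[j].split(",")
            lines[j] = ",".join(fields[i] for i in keep)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError, match="ankle_r"):
            read_trajectories(path)

    def test_non_monotone_timestamps_is_data_error(self, tmp_path):
        traj = make_traj(10)
        path = tmp_path / "bad.csv"
        write_trajectories([traj], path)
        lines = path.read_text().splitlines()
        fields = lines[7].split(",")
        fields[0] = "0.0"
        lines[7] = ",".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DataError, match="increasing"):
            read_trajectories(path)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

class TestSegmentation:
    @pytest.mark.parametrize("seed", range(10))
    def test_scripted_sessions_detected_within_two_frames(self, seed):
        """Detected onsets/offsets match the generator's scripted schedule."""
        rng = np.random.default_rng(seed)
        template = MotionTemplate(
            stature=rng.normal(1.68, 0.02),
            transition_duration=max(0.9, rng.normal(1.3, 0.08)),
        )
        impair = ImpairmentParams(
            trunk_deviation_gain=rng.uniform(0, 0.6),
            le_deviation_gain=rng.uniform(0, 0.5),
            pause_probability=0.2,
        )
        traj = generate_session(template, impair, n_reps=5, seed=rng)
        reps = segment_sts(traj)
        assert len(reps) == 5
        for rep, meta in zip(reps, traj.meta["reps"]):
            assert abs(rep.start_frame - meta["onset_frame"]) <= 2
            assert abs(rep.end_frame - 1 - meta["offset_frame"]) <= 2

    def test_pause_core_excised_from_slice(self):
        template = MotionTemplate()
        impair = ImpairmentParams(pause_probability=1.0)
        traj = generate_session(template, impair, n_reps=3, seed=5)
        reps = segment_sts(traj)
        paused = [m for m in traj.meta["reps"] if m["pause_frames"]]
        assert paused, "scripted session should contain pauses"
        for meta in paused:
            rep = reps[meta["index"] - 1]
            kept = set(rep.frame_indices.tolist())
            core = set(meta["pause_frames"][4:-4])
            assert not (core & kept)

    def test_pause_collapsed_to_motion_time(self):
        """A paused repetition normalizes like an unpaused one."""
        template = MotionTemplate()
        traj_p = generate_session(
            template, ImpairmentParams(pause_probability=1.0), 2, seed=5,
            noise_sd=0.0,
        )
        traj_n = generate_session(
            template, ImpairmentParams(pause_probability=0.0), 2, seed=5,
            noise_sd=0.0,
        )
        rep_p = segment_sts(traj_p)[0]
        rep_n = segment_sts(traj_n)[0]
        norm_p = time_normalize(rep_p, TRUNK, 51)
        norm_n = time_normalize(rep_n, TRUNK, 51)
        # residual difference stems from the short sub-threshold pause edges
        # that legitimately stay in the slice; without gap collapsing the
        # discrepancy is an order of magnitude larger
        assert np.abs(norm_p.coords - norm_n.coords).max() < 0.1

    def test_flat_trace_is_degenerate(self):
        t = np.arange(100) / 30.0
        pos = np.ones((100, 11, 3))
        traj = LandmarkTrajectory("S", "CTRL", "F", 30.0, t, pos)
        with pytest.raises(DegenerateInputError):
            segment_sts(traj)

    def test_single_rise_is_segmentation_error(self):
        traj = generate_session(MotionTemplate(), ImpairmentParams(), 1, seed=0)
        with pytest.raises(SegmentationError, match="1 sit-to-stand"):
            segment_sts(traj)


class TestDropFirst:
    def _reps(self, indices):
        out = []
        for i in indices:
            out.append(STSRepetition(
                repetition_index=i, start_frame=10 * i, end_frame=10 * i + 5,
                frame_indices=np.arange(10 * i, 10 * i + 5),
                timestamps=np.arange(5) / 30.0 + i,
                positions=np.zeros((5, 11, 3)),
            ))
        return out

    def test_five_reps_keep_two_to_five(self):
        kept = drop_first_repetition(self._reps([1, 2, 3, 4, 5]))
        assert [r.repetition_index for r in kept] == [2, 3, 4, 5]

    def test_two_reps_keep_second(self):
        kept = drop_first_repetition(self._reps([1, 2]))
        assert [r.repetition_index for r in kept] == [2]

    def test_single_rep_errors(self):
        with pytest.raises(SegmentationError):
            drop_first_repetition(self._reps([1]))


# ---------------------------------------------------------------------------
# time normalization
# ---------------------------------------------------------------------------

def ramp_rep(n=40, lo=0.0, hi=1.0):
    t = np.arange(n) / 30.0
    pos = np.tile(np.linspace(lo, hi, n)[:, None, None], (1, 11, 3))
    return STSRepetition(
        repetition_index=2, start_frame=0, end_frame=n,
        frame_indices=np.arange(n), timestamps=t, positions=pos,
    )


class TestTimeNormalize:
    def test_grid_spans_unit_interval(self):
        trial = time_normalize(ramp_rep(), FULL_BODY, 101)
        assert trial.normalized_time[0] == 0.0
        assert trial.normalized_time[-1] == 1.0
        assert trial.coords.shape == (101, 33)

    def test_constant_rep_stays_constant(self):
        trial = time_normalize(ramp_rep(lo=0.3, hi=0.3), FULL_BODY, 51)
        assert np.ptp(trial.coords) == 0.0

    def test_linear_ramp_resampled_exactly(self):
        trial = time_normalize(ramp_rep(), FULL_BODY, 76)
        expected = np.linspace(0.0, 1.0, 76)
        np.testing.assert_allclose(trial.coords[:, 0], expected, atol=1e-12)

    def test_idempotent_on_uniform_trials(self):
        first = time_normalize(ramp_rep(37), FULL_BODY, 101)
        rep = STSRepetition(
            repetition_index=2, start_frame=0, end_frame=101,
            frame_indices=np.arange(101),
            timestamps=first.normalized_time,
            positions=first.coords.reshape(101, 11, 3),
        )
        second = time_normalize(rep, FULL_BODY, 101)
        np.testing.assert_allclose(second.coords, first.coords, atol=1e-12)

    def test_landmark_subset_in_canonical_order(self):
        rep = ramp_rep(20)
        rep.positions = rep.positions * np.arange(11)[None, :, None]
        trial = time_normalize(rep, TRUNK, 11)
        # trunk columns must correspond to neck..spine_base in canonical order
        assert trial.coords.shape[1] == 15
        np.testing.assert_allclose(trial.coords[-1, :3], 0.0)      # neck idx 0
        np.testing.assert_allclose(trial.coords[-1, 12:], 4.0)     # spine_base idx 4

    def test_small_grid_is_parameter_error(self):
        with pytest.raises(ParameterError):
            time_normalize(ramp_rep(), FULL_BODY, 1)
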