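"""Landmark-trajectory I/O, sit-to-stand segmentation, and time normalization.

File dialect
------------
A trajectory file is plain comma-delimited text holding one or more
subject-sessions. Each session block starts with a ``#``-prefixed metadata
line carrying ``subject_id``, ``group``, ``sex`` and ``sample_rate``, followed
by a column-header row (``time_s`` then the 33 ``<landmark>_<axis>`` columns
in canonical order) and one row per frame. Coordinates are meters, time is
seconds. Empty fields mark dropped samples; runs of up to
``max_gap_frames`` consecutive missing frames per column are linearly
interpolated on read, longer runs are a data error.

Segmentation
------------
A sit-to-stand repetition is the motion from seated to standing, excluding
pauses. Detection thresholds the smoothed upward vertical velocity of the
``spine_base`` landmark: a repetition runs from the frame that velocity first
exceeds the threshold to the frame it last falls below it within the rise,
with interior sub-threshold plateaus longer than ``max_pause_gap_s`` excised
from the slice. Stand-to-sit descents (sustained negative velocity) separate
repetitions and are never merged across.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    DataError,
    DegenerateInputError,
    ParameterError,
    SchemaError,
    SegmentationError,
)
from .landmarks import COORD_COLUMNS, LANDMARKS, LandmarkSet

_HEADER_COLS = ("time_s",) + COORD_COLUMNS


@dataclass
class LandmarkTrajectory:
    """One subject-session's 11-landmark 3D time series.

    positions has shape ``T x 11 x 3`` (canonical landmark order, axes x/y/z);
    timestamps are strictly increasing seconds. ``meta`` carries optional
    provenance such as a synthetic generator's repetition schedule; it is not
    persisted by the file writer.
    """

    subject_id: str
    group: str
    sex: str
    sample_rate: float
    timestamps: np.ndarray
    positions: np.ndarray
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        t = self.timestamps
        if t.ndim != 1 or t.size < 2:
            raise DataError(f"{self.subject_id}: need at least 2 frames")
        if self.positions.shape != (t.size, len(LANDMARKS), 3):
            raise DataError(
                f"{self.subject_id}: positions shape {self.positions.shape} "
                f"!= ({t.size}, {len(LANDMARKS)}, 3)"
            )
        if not np.all(np.diff(t) > 0):
            raise DataError(f"{self.subject_id}: timestamps not strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise DataError(f"{self.subject_id}: non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size

    def flat_coords(self) -> np.ndarray:
        """T x 33 view of positions in canonical column order."""
        return self.positions.reshape(self.n_frames, -1)


@dataclass
class STSRepetition:
    """One seated-to-standing transition slice of a parent trajectory.

    ``start_frame``/``end_frame`` delimit the transition as a 0-based
    half-open interval in the parent; ``frame_indices`` lists the frames kept
    after excising interior pauses (a subset of ``range(start, end)``).
    """

    repetition_index: int
    start_frame: int
    end_frame: int
    frame_indices: np.ndarray
    timestamps: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        if self.start_frame >= self.end_frame:
            raise ParameterError("start_frame must precede end_frame")

    @property
    def n_frames(self) -> int:
        return self.timestamps.size


@dataclass
class NormalizedTrial:
    """A repetition resampled onto a uniform unit-time grid.

    ``coords`` is ``grid_size x (3 * |landmark set|)``: flattened landmark
    coordinates per normalized time point, enabling cross-subject stacking.
    """

    subject_id: str
    repetition_index: int
    grid_size: int
    normalized_time: np.ndarray
    coords: np.ndarray
    landmark_set: LandmarkSet


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for threshold-based sit-to-stand detection.

    velocity_threshold_ms
        Upward vertical-velocity threshold on spine_base (m/s).
    smoothing_window
        Moving-average window (frames) applied to the velocity signal.
    min_duration_s
        Minimum transition duration; shorter supra-threshold runs are noise.
    max_pause_gap_s
        Interior sub-threshold plateaus longer than this are excised from the
        repetition slice (the "excluding any pauses" rule).
    max_merge_gap_s
        Supra-threshold runs separated by a descent-free gap up to this long
        are one paused repetition, not two.
    min_displacement_m
        Minimum net vertical rise of spine_base for a candidate repetition.
    min_run_frames
        Supra-threshold runs shorter than this are treated as noise chatter
        and ignored (debounce).
    """

    velocity_threshold_ms: float = 0.05
    smoothing_window: int = 5
    min_duration_s: float = 0.5
    max_pause_gap_s: float = 0.3
    max_merge_gap_s: float = 3.0
    min_displacement_m: float = 0.10
    min_run_frames: int = 2


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _format_meta(traj: LandmarkTrajectory) -> str:
    return (
        f"# subject_id={traj.subject_id} group={traj.group} "
        f"sex={traj.sex} sample_rate={traj.sample_rate:g}"
    )


def write_trajectories(trajs: Iterable[LandmarkTrajectory], path) -> None:
    """Write trajectories to the delimited text dialect (lossless to 1e-9)."""
    with open(path, "w") as fh:
        fh.write("# kscore-trajectories v1\n")
        for traj in trajs:
            fh.write(_format_meta(traj) + "\n")
            fh.write(",".join(_HEADER_COLS) + "\n")
            flat = traj.flat_coords()
            for t, row in zip(traj.timestamps, flat):
                fields = [f"{t:.12g}"] + [f"{v:.12g}" for v in row]
                fh.write(",".join(fields) + "\n")


def _parse_meta_line(line: str, lineno: int) -> dict:
    meta: dict = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            raise SchemaError(f"line {lineno}: malformed metadata token {token!r}")
        key, _, value = token.partition("=")
        meta[key] = value
    for key in ("subject_id", "group", "sex", "sample_rate"):
        if key not in meta:
            raise SchemaError(f"line {lineno}: metadata missing {key!r}")
    meta["sample_rate"] = float(meta["sample_rate"])
    return meta


def _fill_gaps(values: np.ndarray, column: str, max_gap: int) -> np.ndarray:
    """Linearly interpolate interior NaN runs of length <= max_gap."""
    bad = ~np.isfinite(values)
    if not bad.any():
        return values
    idx = np.flatnonzero(bad)
    # split into consecutive runs
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    n = values.size
    for run in runs:
        first, last = run[0], run[-1]
        if first == 0 or last == n - 1 or run.size > max_gap:
            raise DataError(
                f"column {column}: gap of {run.size} missing frame(s) at "
                f"frames {first}..{last} exceeds what can be interpolated"
            )
    good = np.flatnonzero(~bad)
    out = values.copy()
    out[bad] = np.interp(idx, good, values[good])
    return out


def read_trajectories(path, max_gap_frames: int = 5) -> list[LandmarkTrajectory]:
    """Read all subject-sessions from a trajectory file.

    Short gaps (``<= max_gap_frames`` consecutive missing frames in a column)
    are linearly interpolated; longer or edge gaps raise :class:`DataError`.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()

    sessions: list[LandmarkTrajectory] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if line.startswith("#"):
            if "subject_id=" not in line:
                i += 1  # file banner / free comment
                continue
            meta = _parse_meta_line(line, i + 1)
            i += 1
            if i >= n or lines[i].startswith("#"):
                raise SchemaError(f"line {i}: session block missing column header")
            header = tuple(c.strip() for c in lines[i].split(","))
            if header != _HEADER_COLS:
                missing = set(_HEADER_COLS) - set(header)
                extra = set(header) - set(_HEADER_COLS)
                raise SchemaError(
                    f"line {i + 1}: bad column header "
                    f"(missing={sorted(missing)}, unexpected={sorted(extra)}, "
                    f"order must be canonical)"
                )
            i += 1
            block_start = i
            while i < n and lines[i].strip() and not lines[i].startswith("#"):
                i += 1
            rows = lines[block_start:i]
            if not rows:
                raise DataError(f"subject {meta['subject_id']}: empty session block")
            table = np.genfromtxt(
                io.StringIO("\n".join(rows)), delimiter=",", dtype=float,
                ndmin=2,
            )
            if table.shape[1] != len(_HEADER_COLS):
                raise SchemaError(
                    f"subject {meta['subject_id']}: row width {table.shape[1]} "
                    f"!= {len(_HEADER_COLS)}"
                )
            timestamps = table[:, 0]
            if not np.all(np.isfinite(timestamps)):
                raise DataError(f"subject {meta['subject_id']}: missing timestamps")
            if not np.all(np.diff(timestamps) > 0):
                raise DataError(
                    f"subject {meta['subject_id']}: timestamps not strictly increasing"
                )
            coords = table[:, 1:]
            for j, col in enumerate(COORD_COLUMNS):
                coords[:, j] = _fill_gaps(coords[:, j], col, max_gap_frames)
            sessions.append(
                LandmarkTrajectory(
                    subject_id=meta["subject_id"],
                    group=meta["group"],
                    sex=meta["sex"],
                    sample_rate=meta["sample_rate"],
                    timestamps=timestamps,
                    positions=coords.reshape(-1, len(LANDMARKS), 3),
                )
            )
        else:
            raise SchemaError(f"line {i + 1}: data outside a session block")
    return sessions


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _smoothed_vertical_velocity(
    traj: LandmarkTrajectory, window: int
) -> np.ndarray:
    y = traj.positions[:, LANDMARKS.index("spine_base"), 1]
    if np.ptp(y) == 0:
        raise DegenerateInputError(
            f"{traj.subject_id}: zero-variance vertical signal on spine_base"
        )
    v = np.gradient(y, traj.timestamps)
    if window > 1:
        kernel = np.ones(window) / window
        v = np.convolve(v, kernel, mode="same")
    return v


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    return [(r[0], r[-1] + 1) for r in np.split(idx, splits)]


def segment_sts(
    traj: LandmarkTrajectory, params: SegmentationParams | None = None
) -> list[STSRepetition]:
    """Detect seated-to-standing rises, excising interior pauses.

    Returns repetitions numbered 1..k in temporal order. Raises
    :class:`SegmentationError` if fewer than 2 rises are found (the
    first-trial-removal rule cannot apply) and
    :class:`DegenerateInputError` on a flat vertical signal.
    """
    params = params or SegmentationParams()
    t = traj.timestamps
    v = _smoothed_vertical_velocity(traj, params.smoothing_window)
    thr = params.velocity_threshold_ms
    above = [
        run for run in _runs_above(v > thr)
        if run[1] - run[0] >= params.min_run_frames
    ]

    # Merge supra-threshold runs separated by descent-free short gaps: a
    # mid-rise pause has near-zero velocity, while a completed stand is
    # followed by a descent with sustained v < -thr.
    merged: list[tuple[int, int]] = []
    for run in above:
        if merged:
            gap_lo, gap_hi = merged[-1][1], run[0]
            gap_dur = t[run[0]] - t[merged[-1][1] - 1]
            if (
                gap_dur <= params.max_merge_gap_s
                and not np.any(v[gap_lo:gap_hi] < -thr)
            ):
                merged[-1] = (merged[-1][0], run[1])
                continue
        merged.append(run)

    y = traj.positions[:, LANDMARKS.index("spine_base"), 1]
    reps: list[STSRepetition] = []
    for start, end in merged:
        if t[end - 1] - t[start] < params.min_duration_s:
            continue
        if y[end - 1] - y[start] < params.min_displacement_m:
            continue  # not a rise (noise run or descent artifact)
        keep = np.ones(end - start, dtype=bool)
        interior = v[start:end] <= thr
        for lo, hi in _runs_above(interior):
            if lo == 0 or hi == end - start:
                continue
            if t[start + hi] - t[start + lo] > params.max_pause_gap_s:
                keep[lo:hi] = False
        frame_indices = np.arange(start, end)[keep]
        # Collapse excised pauses to motion time: the body is stationary
        # during a pause, so the transition resumes where it stopped and the
        # pause contributes one nominal frame interval, not its wall time.
        raw_t = t[frame_indices]
        step = np.diff(raw_t)
        nominal = float(np.median(np.diff(t)))
        gap = np.diff(frame_indices) > 1
        step[gap] = nominal
        motion_t = raw_t[0] + np.concatenate([[0.0], np.cumsum(step)])
        reps.append(
            STSRepetition(
                repetition_index=len(reps) + 1,
                start_frame=start,
                end_frame=end,
                frame_indices=frame_indices,
                timestamps=motion_t,
                positions=traj.positions[frame_indices],
            )
        )
    if len(reps) < 2:
        raise SegmentationError(
            f"{traj.subject_id}: detected {len(reps)} sit-to-stand rise(s); "
            "need at least 2 to apply first-trial removal"
        )
    return reps


def drop_first_repetition(reps: Sequence[STSRepetition]) -> list[STSRepetition]:
    """Remove repetition 1, preserving the original numbering of the rest."""
    if len(reps) < 2:
        raise SegmentationError("need at least 2 repetitions to drop the first")
    return [replace(r) for r in reps if r.repetition_index >= 2]


# ---------------------------------------------------------------------------
# Temporal normalization
# ---------------------------------------------------------------------------

def time_normalize(
    rep: STSRepetition,
    landmark_set: LandmarkSet,
    grid_size: int = 101,
    subject_id: str = "",
) -> NormalizedTrial:
    """Resample one repetition onto a uniform [0, 1] grid.

    The repetition's time axis is min-max mapped to [0, 1] and each retained
    coordinate is linearly interpolated onto ``grid_size`` uniform points.
    Only the requested landmark set's columns are kept, flattened in
    canonical order.
    """
    if grid_size < 2:
        raise ParameterError("grid_size must be >= 2")
    if rep.n_frames < 2:
        raise ParameterError("repetition must span at least 2 frames")
    t = rep.timestamps
    u = (t - t[0]) / (t[-1] - t[0])
    grid = np.linspace(0.0, 1.0, grid_size)
    flat = rep.positions.reshape(rep.n_frames, -1)[:, landmark_set.coord_indices]
    coords = np.empty((grid_size, flat.shape[1]))
    for j in range(flat.shape[1]):
        coords[:, j] = np.interp(grid, u, flat[:, j])
    return NormalizedTrial(
        subject_id=subject_id,
        repetition_index=rep.repetition_index,
        grid_size=grid_size,
        normalized_time=grid,
        coords=coords,
        landmark_set=landmark_set,
    )


def normalize_session(
    traj: LandmarkTrajectory,
    landmark_set: LandmarkSet,
    grid_size: int = 101,
    params: SegmentationParams | None = None,
) -> list[NormalizedTrial]:
    """segment -> drop first -> time-normalize, for one session."""
    reps = drop_first_repetition(segment_sts(traj, params))
    return [
        time_normalize(rep, landmark_set, grid_size, subject_id=traj.subject_id)
        for rep in reps
    ]
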