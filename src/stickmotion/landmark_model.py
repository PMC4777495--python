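"""Containers and I/O for 2D body-landmark time series.

Coordinates follow the image convention: origin top-left, x to the right,
y downwards, units are pixels.  A :class:`LandmarkSeries` stores the
per-frame positions of a fixed set of named landmarks; absent landmarks are
represented as NaN, while infinities are rejected outright.  All downstream
measures use only distances and angles, so the convention matters only when
constructing fixtures or synthetic figures.

Two CSV dialects are supported.  The canonical *long* layout has one row per
(frame, landmark) observation with columns ``frame,landmark,x,y``; the
*wide* layout has one row per frame with ``<name>_x``/``<name>_y`` column
pairs.  Either dialect round-trips exactly (floats are written with
shortest-repr precision).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError, InputFormatError, ParameterError

#: The landmark vocabulary used throughout: head and torso points encoded on
#: a speaking person plus two static lectern corners.
LANDMARK_NAMES: tuple[str, ...] = (
    "forehead",
    "throat",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_hand",
    "right_hand",
    "navel",
    "lectern_left",
    "lectern_right",
)


@dataclass(frozen=True)
class LandmarkSeries:
    """Per-frame 2D positions of named landmarks.

    Parameters
    ----------
    stimulus_id
        Identifier of the clip / stimulus the series was encoded from.
    frames
        Strictly increasing, non-negative integer frame indices.
    landmarks
        Names of the encoded landmarks (a subset of :data:`LANDMARK_NAMES`).
    positions
        Array of shape ``(n_frames, n_landmarks, 2)``; ``NaN`` marks a
        landmark that is absent in a frame.
    """

    stimulus_id: str
    frames: np.ndarray
    landmarks: tuple[str, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        positions = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "landmarks", tuple(self.landmarks))
        object.__setattr__(self, "positions", positions)
        if frames.ndim != 1 or frames.size == 0:
            raise DataValidationError("a series needs at least one frame")
        if np.any(frames < 0):
            raise DataValidationError("frame indices must be non-negative")
        if np.any(np.diff(frames) <= 0):
            raise DataValidationError("frame indices must be strictly increasing")
        unknown = set(self.landmarks) - set(LANDMARK_NAMES)
        if unknown:
            raise DataValidationError(f"unknown landmark name(s): {sorted(unknown)}")
        if len(set(self.landmarks)) != len(self.landmarks):
            raise DataValidationError("duplicate landmark names")
        if positions.shape != (frames.size, len(self.landmarks), 2):
            raise DataValidationError(
                f"positions shape {positions.shape} does not match "
                f"({frames.size}, {len(self.landmarks)}, 2)"
            )
        if np.any(np.isinf(positions)):
            raise DataValidationError("coordinates must be finite (NaN marks absence)")

    @property
    def n_frames(self) -> int:
        return int(self.frames.size)

    def landmark_index(self, name: str) -> int:
        try:
            return self.landmarks.index(name)
        except ValueError:
            raise DataValidationError(
                f"landmark {name!r} not present in series {self.stimulus_id!r}"
            ) from None

    def trajectory(self, name: str) -> np.ndarray:
        """Positions of one landmark over time, shape ``(n_frames, 2)``."""
        return self.positions[:, self.landmark_index(name), :]

    def to_long(self) -> pd.DataFrame:
        """Long-format view with columns ``frame, landmark, x, y``.

        Rows for absent (NaN) landmark observations are dropped.
        """
        n_f, n_l = self.positions.shape[:2]
        df = pd.DataFrame(
            {
                "frame": np.repeat(self.frames, n_l),
                "landmark": np.tile(np.asarray(self.landmarks, dtype=object), n_f),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
            }
        )
        present = ~(df["x"].isna() & df["y"].isna())
        return df.loc[present].reset_index(drop=True)


@dataclass(frozen=True)
class MotionTrace:
    """A single 2D time series summarising whole-body motion.

    Obtained by summing selected landmark coordinates per frame (see
    :func:`aggregate_trace`) or generated synthetically.  ``frame_rate`` is
    carried as metadata only: every kinematic quantity in this package is
    expressed per frame.
    """

    stimulus_id: str
    points: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        points = np.asarray(self.points, dtype=np.float64)
        object.__setattr__(self, "points", points)
        if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 1:
            raise DataValidationError("trace points must have shape (n>=1, 2)")
        if not np.all(np.isfinite(points)):
            raise DataValidationError("trace coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class SkeletonTopology:
    """Which landmarks feed the motion trace and the limb-angle chains.

    ``chains`` are ordered landmark paths along which static angularity is
    measured (throat -> shoulder -> elbow -> hand on each side);
    ``aggregation_set`` lists the landmarks whose coordinates are summed
    into the single motion trace: the forehead for head movement, the left
    shoulder for torso movement, and both hands for arm movement.
    """

    chains: tuple[tuple[str, ...], ...] = (
        ("throat", "right_shoulder", "right_elbow", "right_hand"),
        ("throat", "left_shoulder", "left_elbow", "left_hand"),
    )
    aggregation_set: tuple[str, ...] = (
        "forehead",
        "left_shoulder",
        "left_hand",
        "right_hand",
    )

    def __post_init__(self) -> None:
        for chain in self.chains:
            if len(set(chain)) != len(chain):
                raise DataValidationError(f"chain has repeated landmarks: {chain}")
        for name in self.chain_landmarks() + tuple(self.aggregation_set):
            if name not in LANDMARK_NAMES:
                raise DataValidationError(f"unknown landmark name: {name!r}")

    def chain_landmarks(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for chain in self.chains:
            for name in chain:
                seen.setdefault(name)
        return tuple(seen)


#: Default topology used by the feature-extraction pipeline.
DEFAULT_TOPOLOGY = SkeletonTopology()


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _series_from_long(df: pd.DataFrame, stimulus_id: str) -> LandmarkSeries:
    required = {"frame", "landmark", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise InputFormatError(f"long landmark CSV is missing columns {sorted(missing)}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise InputFormatError(
                f"non-numeric {col!r} value {df[col].iloc[row]!r} at row {row}"
            )
        df[col] = coerced
    frame_col = pd.to_numeric(df["frame"], errors="coerce")
    if frame_col.isna().any() or np.any(frame_col % 1 != 0):
        raise InputFormatError("frame indices must be integers")
    df["frame"] = frame_col.astype(np.int64)
    dup = df.duplicated(subset=["frame", "landmark"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = (int(df["frame"].iloc[row]), str(df["landmark"].iloc[row]))
        raise InputFormatError(f"duplicate (frame, landmark) entry {key}")

    frames = np.sort(df["frame"].unique())
    names = tuple(sorted(df["landmark"].unique()))
    frame_pos = {f: i for i, f in enumerate(frames)}
    name_pos = {l: j for j, l in enumerate(names)}
    positions = np.full((frames.size, len(names), 2), np.nan)
    rows = df["frame"].map(frame_pos).to_numpy()
    cols = df["landmark"].map(name_pos).to_numpy()
    positions[rows, cols, 0] = df["x"].to_numpy()
    positions[rows, cols, 1] = df["y"].to_numpy()
    return LandmarkSeries(stimulus_id, frames, names, positions)


def _series_from_wide(df: pd.DataFrame, stimulus_id: str) -> LandmarkSeries:
    if "frame" not in df.columns:
        raise InputFormatError("wide landmark CSV is missing the 'frame' column")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            name = col[:-2]
            if f"{name}_y" not in df.columns:
                raise InputFormatError(f"column {col!r} lacks its {name}_y pair")
            names.append(name)
    stray = [
        c
        for c in df.columns
        if c != "frame" and c[:-2] not in names
    ]
    if stray:
        raise InputFormatError(f"unrecognised wide columns {stray}")
    if not names:
        raise InputFormatError("wide landmark CSV contains no <name>_x/<name>_y pairs")
    long = df.melt(id_vars="frame", var_name="key", value_name="value")
    long["landmark"] = long["key"].str[:-2]
    long["axis"] = long["key"].str[-1]
    pivot = long.pivot_table(
        index=["frame", "landmark"], columns="axis", values="value", aggfunc="first"
    ).reset_index()
    pivot.columns.name = None
    return _series_from_long(pivot[["frame", "landmark", "x", "y"]], stimulus_id)


def read_landmark_series(
    path: str | Path, dialect: str = "long", stimulus_id: str | None = None
) -> LandmarkSeries:
    """Read a landmark CSV in the ``long`` or ``wide`` dialect.

    ``stimulus_id`` defaults to the file stem.  Frames are sorted ascending;
    duplicated (frame, landmark) observations and non-numeric coordinates
    raise :class:`InputFormatError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such landmark file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    sid = stimulus_id if stimulus_id is not None else path.stem
    if dialect == "long":
        return _series_from_long(df, sid)
    if dialect == "wide":
        return _series_from_wide(df, sid)
    raise ParameterError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")


def write_landmark_series(
    series: LandmarkSeries, path: str | Path, dialect: str = "long"
) -> None:
    """Write a series to CSV in either dialect (lossless round trip)."""
    path = Path(path)
    if dialect == "long":
        series.to_long().to_csv(path, index=False)
    elif dialect == "wide":
        data: dict[str, np.ndarray] = {"frame": series.frames}
        for j, name in enumerate(series.landmarks):
            data[f"{name}_x"] = series.positions[:, j, 0]
            data[f"{name}_y"] = series.positions[:, j, 1]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ParameterError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")


# ---------------------------------------------------------------------------
# Stride interpolation and aggregation
# ---------------------------------------------------------------------------

def interpolate_stride(series: LandmarkSeries, stride: int) -> LandmarkSeries:
    """Fill in frames skipped during encoding by linear interpolation.

    Encoding every ``stride``-th video frame keeps the manual workload down;
    this restores a step-1 series by interpolating each coordinate linearly
    between its bracketing keyframes.  Keyframe values are preserved
    bit-exactly and nothing is extrapolated beyond the last keyframe.
    """
    if int(stride) != stride or stride < 1:
        raise ParameterError(f"stride must be a positive integer, got {stride!r}")
    stride = int(stride)
    if np.any(series.frames % stride != 0):
        off = series.frames[series.frames % stride != 0]
        raise InputFormatError(
            f"keyframes {off.tolist()} are not multiples of stride {stride}"
        )
    if np.any(np.isnan(series.positions)):
        f, l = np.argwhere(np.isnan(series.positions).any(axis=2))[0]
        raise DataValidationError(
            f"cannot interpolate: landmark {series.landmarks[l]!r} absent in "
            f"frame {int(series.frames[f])}"
        )
    new_frames = np.arange(series.frames[0], series.frames[-1] + 1, dtype=np.int64)
    n_l = len(series.landmarks)
    out = np.empty((new_frames.size, n_l, 2))
    for j in range(n_l):
        for axis in range(2):
            out[:, j, axis] = np.interp(
                new_frames, series.frames, series.positions[:, j, axis]
            )
    # np.interp is exact at sample points only up to rounding; pin keyframes.
    key_rows = series.frames - series.frames[0]
    out[key_rows] = series.positions
    return replace(series, frames=new_frames, positions=out)


def aggregate_trace(
    series: LandmarkSeries, topology: SkeletonTopology = DEFAULT_TOPOLOGY
) -> MotionTrace:
    """Sum the topology's aggregation landmarks into a single motion trace.

    Point ``t`` is the component-wise sum of the selected landmarks'
    positions at frame ``t``, yielding one 2D series that carries head,
    torso and arm motion together.
    """
    total = np.zeros((series.n_frames, 2))
    for name in topology.aggregation_set:
        traj = series.trajectory(name)
        bad = np.flatnonzero(np.isnan(traj).any(axis=1))
        if bad.size:
            raise DataValidationError(
                f"landmark {name!r} absent in frame {int(series.frames[bad[0]])} "
                f"of series {series.stimulus_id!r}"
            )
        total += traj
    return MotionTrace(series.stimulus_id, total)
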