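"""Direction-change segmentation and the four motion/angularity measures.

The central primitive is a reference-point scan over a single 2D motion
trace.  Starting from the first frame, Euclidean distances to successive
frames are accumulated until the distance starts to fall; the frame of peak
distance closes one *motion unit* (a maximum), becomes the new reference,
and the scan resumes.  Gesturing is roughly pendulum-like, so each unit
corresponds to one excursion of the body before a change of direction.

From the chained units four scalar descriptors of a clip are derived:

``n_maxima``
    the number of motion units — a count of direction changes,
``avg_velocity``
    mean of per-unit peak distance divided by elapsed frames (px/frame),
``avg_turn_angle``
    mean unsigned angle in degrees between successive inter-reference
    displacement vectors (0 deg = straight continuation, 180 deg = reversal),
``avg_bodypart_angle``
    a static-angularity estimate: the per-frame sum of four limb angles
    (shoulder/upper-arm and upper-arm/forearm on both sides, 0 deg =
    extended), averaged over frames.

Measures that cannot be computed (no units, fewer than two units, missing
limb landmarks) are reported as ``None`` — never silently as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DataValidationError, ParameterError
from .landmark_model import (
    DEFAULT_TOPOLOGY,
    LandmarkSeries,
    MotionTrace,
    SkeletonTopology,
    aggregate_trace,
)


@dataclass(frozen=True)
class MotionSegment:
    """One motion unit of the reference-point scan.

    ``trailing`` marks a final excursion closed by the end of the series
    rather than by a detected decrease in distance.
    """

    ref_frame: int
    max_frame: int
    max_distance: float
    trailing: bool = False

    def __post_init__(self) -> None:
        if self.max_frame <= self.ref_frame:
            raise DataValidationError("segment must span at least one frame")
        if self.max_distance < 0:
            raise DataValidationError("max_distance must be non-negative")

    @property
    def elapsed(self) -> int:
        return self.max_frame - self.ref_frame


@dataclass(frozen=True)
class SegmentationResult:
    """Chained motion units for one stimulus."""

    stimulus_id: str
    segments: tuple[MotionSegment, ...]
    epsilon: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.ref_frame != prev.max_frame:
                raise DataValidationError(
                    "segments must chain: each ref_frame equals the previous max_frame"
                )

    @property
    def n_maxima(self) -> int:
        return len(self.segments)

    def reference_frames(self) -> list[int]:
        """Frame indices of the reference points, including the start frame."""
        if not self.segments:
            return []
        return [self.segments[0].ref_frame] + [s.max_frame for s in self.segments]


@dataclass(frozen=True)
class MotionFeatureVector:
    """The four per-stimulus measures plus extraction metadata."""

    stimulus_id: str
    n_maxima: int
    avg_velocity: float | None
    avg_turn_angle: float | None
    avg_bodypart_angle: float | None
    n_frames: int
    epsilon: float


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    dx = a[0] - b[0]
    dy = a[1] - b[1]
    return math.sqrt(dx * dx + dy * dy)


def segment_maxima(trace: MotionTrace, epsilon: float = 0.0) -> SegmentationResult:
    """Run the reference-point scan over a trace.

    A maximum is declared at frame ``t`` when the distance from the current
    reference strictly decreases at ``t + 1`` and the distance at ``t``
    exceeds ``epsilon``; ties (equal distances) extend the scan, so a
    plateau resolves to its last frame.  The maximum's frame becomes the new
    reference and scanning resumes from the following frame.  If the series
    ends while the running distance still exceeds ``epsilon``, a trailing
    segment ending at the final frame is emitted with ``trailing=True``.

    ``epsilon`` (pixels, default 0) suppresses sub-threshold jitter maxima.
    """
    if trace.n_frames < 2:
        raise DataValidationError("segmentation needs a trace of at least 2 frames")
    if epsilon < 0:
        raise ParameterError(f"epsilon must be non-negative, got {epsilon}")
    pts = trace.points
    n = trace.n_frames
    segments: list[MotionSegment] = []
    ref = 0
    prev_d: float | None = None
    i = ref + 1
    while i < n:
        d = _dist(pts[i], pts[ref])
        if prev_d is not None and d < prev_d and prev_d > epsilon:
            segments.append(MotionSegment(ref, i - 1, prev_d, trailing=False))
            ref = i - 1
            prev_d = None
            # re-evaluate frame i against the new reference
            continue
        prev_d = d
        i += 1
    if prev_d is not None and prev_d > epsilon:
        segments.append(MotionSegment(ref, n - 1, prev_d, trailing=True))
    return SegmentationResult(trace.stimulus_id, tuple(segments), float(epsilon))


def count_maxima(seg: SegmentationResult) -> int:
    """Number of motion units — the quantity-of-motion measure."""
    return seg.n_maxima


def segment_velocity(segment: MotionSegment) -> float:
    """Peak distance divided by the frames needed to reach it (px/frame)."""
    return segment.max_distance / segment.elapsed


def average_velocity(seg: SegmentationResult) -> float | None:
    """Mean per-unit velocity, or ``None`` when there are no units."""
    if not seg.segments:
        return None
    return float(np.mean([segment_velocity(s) for s in seg.segments]))


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float | None:
    """Unsigned angle between two vectors in degrees; None for a zero vector."""
    nu = math.sqrt(u[0] * u[0] + u[1] * u[1])
    nv = math.sqrt(v[0] * v[0] + v[1] * v[1])
    if nu == 0.0 or nv == 0.0:
        return None
    c = (u[0] * v[0] + u[1] * v[1]) / (nu * nv)
    return math.degrees(math.acos(min(1.0, max(-1.0, c))))


def turning_angles(seg: SegmentationResult, trace: MotionTrace) -> list[float]:
    """Angles between successive inter-reference displacement vectors.

    Direction vector ``k`` runs from reference point ``k`` to reference
    point ``k + 1`` in trace coordinates; each consecutive pair yields one
    unsigned angle (0 deg = same heading, 180 deg = reversal).  Pairs
    containing a zero-length vector are skipped.  With fewer than two
    segments the list is empty.
    """
    refs = seg.reference_frames()
    if len(refs) < 3:
        return []
    points = trace.points[refs]
    vectors = np.diff(points, axis=0)
    angles: list[float] = []
    for u, v in zip(vectors, vectors[1:]):
        a = _angle_deg(u, v)
        if a is not None:
            angles.append(a)
    return angles


def average_turn_angle(angles: Sequence[float]) -> float | None:
    """Arithmetic mean of turning angles, or ``None`` on an empty list."""
    if len(angles) == 0:
        return None
    return float(np.mean(angles))


def bodypart_angle_per_frame(
    series: LandmarkSeries,
    topology: SkeletonTopology = DEFAULT_TOPOLOGY,
    frame: int = 0,
) -> float:
    """Sum of the four limb angles at one frame (degrees, in [0, 720]).

    Per side, two chain turning angles are measured: between the shoulder
    segment (throat -> shoulder) and the upper arm (shoulder -> elbow), and
    between the upper arm and the forearm (elbow -> hand).  Each is the
    unsigned angle between direction vectors, so 0 deg means the chain
    continues straight (fully extended arm) and 180 deg means folded back.
    Zero-length limb segments contribute 0 and are skipped.
    """
    try:
        row = int(np.flatnonzero(series.frames == frame)[0])
    except IndexError:
        raise DataValidationError(
            f"frame {frame} not present in series {series.stimulus_id!r}"
        ) from None
    total = 0.0
    for chain in topology.chains:
        pts = []
        for name in chain:
            p = series.trajectory(name)[row]
            if np.isnan(p).any():
                raise DataValidationError(
                    f"landmark {name!r} absent in frame {frame} of "
                    f"series {series.stimulus_id!r}"
                )
            pts.append(p)
        segs = [pts[i + 1] - pts[i] for i in range(len(pts) - 1)]
        for u, v in zip(segs, segs[1:]):
            a = _angle_deg(u, v)
            if a is not None:
                total += a
    return total


def average_bodypart_angle(
    series: LandmarkSeries, topology: SkeletonTopology = DEFAULT_TOPOLOGY
) -> float:
    """Per-frame limb-angle sum averaged across all frames of the series."""
    sums = [
        bodypart_angle_per_frame(series, topology, int(f)) for f in series.frames
    ]
    return float(np.mean(sums))


def extract_features(
    series: LandmarkSeries,
    topology: SkeletonTopology = DEFAULT_TOPOLOGY,
    epsilon: float = 0.0,
) -> MotionFeatureVector:
    """Aggregate, segment, and compute all four measures for one stimulus.

    The static-angularity measure is ``None`` when the series lacks any
    chain landmark; the motion measures are ``None`` when undefined (no
    units, or fewer than two units for the turning angle).
    """
    trace = aggregate_trace(series, topology)
    seg = segment_maxima(trace, epsilon)
    angles = turning_angles(seg, trace)
    have_chains = bool(topology.chains) and all(
        name in series.landmarks for name in topology.chain_landmarks()
    )
    bodypart = average_bodypart_angle(series, topology) if have_chains else None
    return MotionFeatureVector(
        stimulus_id=series.stimulus_id,
        n_maxima=count_maxima(seg),
        avg_velocity=average_velocity(seg),
        avg_turn_angle=average_turn_angle(angles),
        avg_bodypart_angle=bodypart,
        n_frames=series.n_frames,
        epsilon=float(epsilon),
    )


def features_to_frame(features: Sequence[MotionFeatureVector]):
    """Tabulate feature vectors; undefined measures become NaN/empty cells."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "stimulus_id": f.stimulus_id,
                "n_maxima": f.n_maxima,
                "avg_velocity": f.avg_velocity,
                "avg_turn_angle": f.avg_turn_angle,
                "avg_bodypart_angle": f.avg_bodypart_angle,
                "n_frames": f.n_frames,
                "epsilon": f.epsilon,
            }
            for f in features
        ]
    )
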