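"""Synthetic stimuli with planted, decodable structure.

Real stimuli in this problem domain are stick-figure animations encoded
from videos of speakers; none ship with the package, so every pipeline
stage is exercised against generated data whose ground truth is known:

* :func:`generate_trace` builds a piecewise 2D path from planted
  direction-change units (amplitudes, durations, turning angles),
* :func:`generate_stickfigure_series` wraps such a path in a full
  13-landmark skeleton with controllable arm articulation,
* :func:`generate_ratings` builds a rater panel whose mean ratings
  correlate with a planted feature at a chosen loading,
* :func:`simulate_forced_choice` simulates two-alternative choices driven
  by a logistic rule on the feature difference.

Motion units are constructed so that the reference-point scan recovers them
exactly when jitter is zero.  A unit is one outward excursion of amplitude
``A`` over ``D`` frames; at a unit boundary the path first steps straight
back towards the previous reference point and then sweeps outward to the
next one while its distance from the new reference grows strictly
monotonically.  The back-step guarantees the scan sees a strict distance
decrease at every boundary (a shallow heading change alone would leave the
distance growing and the boundary invisible), and the monotone sweep
guarantees no spurious maxima inside a unit.  For near-reversal turning
angles the sweep degenerates to the straight out-and-back path of a
pendulum.  The planted turning angle between successive inter-reference
vectors is exact by construction.

All randomness flows from the explicit ``seed`` in each config; identical
configs produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError, ParameterError
from .landmark_model import LandmarkSeries, MotionTrace
from .stats_suite import RatingMatrix, TrialRecord, WORDS


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionGenConfig:
    """Parameters of the piecewise motion-unit generator.

    Defaults describe a speaker gesturing at a lectern for roughly a
    15-second clip: about 40 direction changes, excursions of ~30 px lasting
    ~10 frames, mostly pendulum-like (mean heading change 150 deg with
    moderate concentration), and no frame jitter.
    """

    n_segments: int = 40
    amplitude_mean: float = 30.0
    amplitude_sd: float = 8.0
    duration_mean: float = 10.0
    duration_sd: float = 3.0
    heading_change_mean: float = 150.0  # degrees in [0, 180]
    heading_concentration: float = 4.0  # von Mises kappa
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ParameterError("n_segments must be >= 1")
        if self.amplitude_mean <= 0:
            raise ParameterError("amplitude_mean must be positive")
        if self.duration_mean < 1:
            raise ParameterError("duration_mean must be >= 1")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be non-negative")
        if not (0 <= self.heading_change_mean <= 180):
            raise ParameterError("heading_change_mean must lie in [0, 180] degrees")


@dataclass(frozen=True)
class RaterGenConfig:
    """Parameters of the synthetic rater panel.

    ``loading`` is the target correlation between the planted feature and
    the panel-mean rating (planted at the stimulus level, before
    independent per-rater noise, so rater noise attenuates the recovered
    correlation only by ``noise_sd / sqrt(n_raters)``).  ``signal_sd``
    scales stimulus-level rating spread in scale units.
    """

    n_raters: int = 25
    loading: float = 0.5
    noise_sd: float = 20.0
    signal_sd: float = 30.0
    bounds: tuple[float, float] = (-100.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.loading) > 1:
            raise ParameterError("loading must lie in [-1, 1]")
        if self.n_raters < 1:
            raise ParameterError("n_raters must be >= 1")
        if self.noise_sd < 0 or self.signal_sd <= 0:
            raise ParameterError("noise_sd must be >= 0 and signal_sd > 0")


@dataclass(frozen=True)
class ChoiceSimConfig:
    """Parameters of the simulated forced-choice observer.

    ``sensitivity`` is the slope of a logistic choice rule applied to the
    (high - low) feature difference; 0 yields chance performance and
    ``math.inf`` a deterministic observer.
    """

    n_trials: int = 460
    sensitivity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        if self.sensitivity < 0:
            raise ParameterError("sensitivity must be non-negative")


@dataclass(frozen=True)
class TracePlan:
    """Ground truth planted into a generated trace."""

    ref_frames: np.ndarray       # frame index of each reference point (incl. start)
    ref_points: np.ndarray       # noiseless coordinates of the reference points
    amplitudes: np.ndarray       # per-unit excursion length (px)
    durations: np.ndarray        # per-unit length in frames
    turn_angles: np.ndarray      # degrees between successive unit vectors

    @property
    def velocities(self) -> np.ndarray:
        return self.amplitudes / self.durations


# ---------------------------------------------------------------------------
# Trace generation
# ---------------------------------------------------------------------------

def _fold_angle(theta: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi] and take the magnitude -> [0, pi]."""
    return np.abs(np.mod(theta + np.pi, 2 * np.pi) - np.pi)


def generate_trace_detailed(config: MotionGenConfig) -> tuple[MotionTrace, TracePlan]:
    """Generate a motion trace together with its planted ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_segments
    amps = rng.normal(config.amplitude_mean, config.amplitude_sd, n)
    amps = np.clip(
        amps, 0.2 * config.amplitude_mean, config.amplitude_mean + 4 * config.amplitude_sd
    )
    durs = np.rint(rng.normal(config.duration_mean, config.duration_sd, n))
    durs = np.clip(durs, 2, None).astype(int)
    raw = rng.vonmises(
        math.radians(config.heading_change_mean), config.heading_concentration, n - 1
    )
    turns = _fold_angle(raw)
    signs = rng.choice([-1.0, 1.0], size=n - 1)

    headings = np.empty(n)
    headings[0] = rng.uniform(0, 2 * np.pi)
    for k in range(1, n):
        headings[k] = headings[k - 1] + signs[k - 1] * turns[k - 1]

    ref_points = np.zeros((n + 1, 2))
    for k in range(n):
        ref_points[k + 1] = ref_points[k] + amps[k] * np.array(
            [math.cos(headings[k]), math.sin(headings[k])]
        )

    points = [ref_points[0]]
    for k in range(n):
        d = durs[k]
        if k == 0:
            # first unit: straight outward motion
            radii = amps[k] * np.arange(1, d + 1) / d
            phis = np.full(d, headings[k])
        else:
            # back-step then monotone outward sweep to the next reference
            phi_start = headings[k - 1] + math.pi
            delta = math.remainder(headings[k] - phi_start, 2 * math.pi)
            phis = phi_start + delta * np.arange(0, d) / (d - 1)
            r1 = min(amps[k] / d, 0.5 * amps[k - 1])
            radii = r1 + (amps[k] - r1) * np.arange(0, d) / (d - 1)
        seg_pts = ref_points[k] + radii[:, None] * np.column_stack(
            (np.cos(phis), np.sin(phis))
        )
        seg_pts[-1] = ref_points[k + 1]  # exact landing on the reference point
        points.extend(seg_pts)
    pts = np.asarray(points)
    if config.jitter_sd > 0:
        pts = pts + rng.normal(0.0, config.jitter_sd, pts.shape)

    plan = TracePlan(
        ref_frames=np.concatenate(([0], np.cumsum(durs))),
        ref_points=ref_points,
        amplitudes=amps,
        durations=durs,
        turn_angles=np.degrees(turns),
    )
    return MotionTrace(f"synthetic-{config.seed}", pts), plan


def generate_trace(config: MotionGenConfig) -> MotionTrace:
    """Generate a motion trace (see :func:`generate_trace_detailed`)."""
    return generate_trace_detailed(config)[0]


# ---------------------------------------------------------------------------
# Stick-figure series
# ---------------------------------------------------------------------------

_BODY_OFFSETS: dict[str, tuple[float, float]] = {
    # body coordinates, y down; throat at the origin, head above (negative y)
    "throat": (0.0, 0.0),
    "forehead": (0.0, -60.0),
    "left_ear": (-25.0, -55.0),
    "right_ear": (25.0, -55.0),
    "left_shoulder": (-40.0, 0.0),
    "right_shoulder": (40.0, 0.0),
    "navel": (0.0, 80.0),
}

_LECTERN = {"lectern_left": (320.0, 560.0), "lectern_right": (680.0, 560.0)}

_UPPER_ARM = 45.0
_FOREARM = 40.0


def _rotate(v: np.ndarray, deg: float) -> np.ndarray:
    rad = math.radians(deg)
    c, s = math.cos(rad), math.sin(rad)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _skeleton_frame(
    origin: np.ndarray, shoulder_deg_r: float, flexion_deg_r: float,
    shoulder_deg_l: float, flexion_deg_l: float,
) -> dict[str, np.ndarray]:
    """Landmark positions for one frame given arm joint angles.

    Joint angles follow the chain-turning convention: 0 deg keeps the chain
    collinear with the previous segment (arm extended sideways along the
    shoulder line), positive values rotate the limb downward (+y).
    """
    pos = {name: origin + np.array(off) for name, off in _BODY_OFFSETS.items()}
    for side, shoulder_deg, flexion_deg in (
        ("right", shoulder_deg_r, flexion_deg_r),
        ("left", shoulder_deg_l, flexion_deg_l),
    ):
        sign = 1.0 if side == "right" else -1.0
        shoulder = pos[f"{side}_shoulder"]
        shoulder_dir = np.array([sign, 0.0])  # throat -> shoulder direction
        upper_dir = _rotate(shoulder_dir, sign * shoulder_deg)
        elbow = shoulder + _UPPER_ARM * upper_dir
        fore_dir = _rotate(upper_dir, sign * flexion_deg)
        hand = elbow + _FOREARM * fore_dir
        pos[f"{side}_elbow"] = elbow
        pos[f"{side}_hand"] = hand
    for name, p in _LECTERN.items():
        pos[name] = np.asarray(p, dtype=float)
    return pos


def _assemble_series(
    stimulus_id: str, frames: np.ndarray, per_frame: list[dict[str, np.ndarray]]
) -> LandmarkSeries:
    names = tuple(sorted(per_frame[0]))
    positions = np.empty((len(per_frame), len(names), 2))
    for t, posmap in enumerate(per_frame):
        for j, name in enumerate(names):
            positions[t, j] = posmap[name]
    return LandmarkSeries(stimulus_id, frames, names, positions)


def static_stickfigure_series(
    n_frames: int = 10,
    flexion_deg: float = 0.0,
    shoulder_deg: float = 0.0,
    stimulus_id: str = "static",
) -> LandmarkSeries:
    """A motionless figure holding a fixed posture — handy for fixtures."""
    origin = np.array([500.0, 300.0])
    posmap = _skeleton_frame(origin, shoulder_deg, flexion_deg, shoulder_deg, flexion_deg)
    frames = np.arange(n_frames, dtype=np.int64)
    return _assemble_series(stimulus_id, frames, [posmap] * n_frames)


def generate_stickfigure_series(
    config: MotionGenConfig,
    flexion_mean: float = 40.0,
    flexion_amp: float = 30.0,
    flexion_period: float = 40.0,
    shoulder_deg: float = 10.0,
    stimulus_id: str | None = None,
) -> LandmarkSeries:
    """Full 13-landmark series whose aggregate trace is a generated path.

    The rigid body (head, torso, shoulders) translates along one quarter of
    the generated trace, so the four-landmark aggregation sum reproduces
    the planted trace up to a constant offset when the arms are still.
    Elbow flexion oscillates sinusoidally between
    ``flexion_mean +/- flexion_amp`` degrees (clipped to [0, 180]) with the
    given period in frames, phase-shifted between sides, so static
    angularity spans its full range.  Lectern corners stay fixed.
    """
    trace = generate_trace(config)
    base = np.array([500.0, 300.0])
    frames = np.arange(trace.n_frames, dtype=np.int64)
    per_frame = []
    for t in range(trace.n_frames):
        origin = base + trace.points[t] / 4.0
        flex_r = flexion_mean + flexion_amp * math.sin(2 * math.pi * t / flexion_period)
        flex_l = flexion_mean + flexion_amp * math.sin(
            2 * math.pi * t / flexion_period + math.pi / 2
        )
        per_frame.append(
            _skeleton_frame(
                origin,
                shoulder_deg,
                float(np.clip(flex_r, 0.0, 180.0)),
                shoulder_deg,
                float(np.clip(flex_l, 0.0, 180.0)),
            )
        )
    sid = stimulus_id if stimulus_id is not None else f"stickfigure-{config.seed}"
    return _assemble_series(sid, frames, per_frame)


# ---------------------------------------------------------------------------
# Rating panels
# ---------------------------------------------------------------------------

def generate_ratings(
    features: Mapping[str, float] | pd.Series,
    config: RaterGenConfig,
    scale_label: str = "takete_maluma",
) -> RatingMatrix:
    """Rater panel whose mean ratings track a planted feature.

    The stimulus-level mean rating is ``signal_sd * (loading * z +
    sqrt(1 - loading^2) * e)`` with ``z`` the z-scored feature and ``e``
    independent standard normal draws, so the expected correlation between
    feature and panel mean equals ``loading``.  Per-rater scores add
    Gaussian noise and are clipped to the scale bounds.
    """
    series = pd.Series(dict(features)) if not isinstance(features, pd.Series) else features
    f = series.to_numpy(dtype=float)
    if f.size < 3:
        raise DataValidationError("need at least 3 stimuli to plant a correlation")
    if np.std(f) == 0:
        raise DataValidationError("feature has zero variance; loading is undefined")
    rng = np.random.default_rng(config.seed)
    z = (f - f.mean()) / f.std()
    eps = rng.standard_normal(f.size)
    mean_rating = config.signal_sd * (
        config.loading * z + math.sqrt(1 - config.loading**2) * eps
    )
    scores = mean_rating[None, :] + rng.normal(
        0.0, config.noise_sd, (config.n_raters, f.size)
    )
    lo, hi = config.bounds
    values = pd.DataFrame(
        np.clip(scores, lo, hi),
        index=[f"rater{r:03d}" for r in range(config.n_raters)],
        columns=[str(s) for s in series.index],
    )
    return RatingMatrix(values, scale_label=scale_label)


# ---------------------------------------------------------------------------
# Forced-choice simulation
# ---------------------------------------------------------------------------

def simulate_forced_choice(
    low_features: Mapping[str, float] | pd.Series,
    high_features: Mapping[str, float] | pd.Series,
    config: ChoiceSimConfig,
    rounds_per_rater: int = 10,
) -> list[TrialRecord]:
    """Simulate two-alternative word-to-motion assignment trials.

    Each trial draws one low- and one high-feature stimulus and a word
    uniformly at random.  The probability of a prediction-consistent choice
    (high stimulus for *takete*, low for *maluma*) is
    ``sigmoid(sensitivity * (f_high - f_low))``; ``sensitivity = inf``
    makes the observer deterministic, 0 makes it guess.
    """
    low = pd.Series(dict(low_features)) if not isinstance(low_features, pd.Series) else low_features
    high = pd.Series(dict(high_features)) if not isinstance(high_features, pd.Series) else high_features
    if low.empty or high.empty:
        raise DataValidationError("both stimulus groups must be non-empty")
    rng = np.random.default_rng(config.seed)
    records = []
    for t in range(config.n_trials):
        low_id = str(rng.choice(low.index))
        high_id = str(rng.choice(high.index))
        word = WORDS[int(rng.integers(2))]
        diff = float(high[high_id] - low[low_id])
        if math.isinf(config.sensitivity):
            p_consistent = 1.0 if diff > 0 else (0.5 if diff == 0 else 0.0)
        else:
            p_consistent = 1.0 / (1.0 + math.exp(-config.sensitivity * diff))
        consistent = bool(rng.random() < p_consistent)
        if word == "takete":
            chosen = high_id if consistent else low_id
            correct = chosen == high_id
        else:
            chosen = low_id if consistent else high_id
            correct = chosen == low_id
        records.append(
            TrialRecord(
                trial_id=t,
                rater_id=t // rounds_per_rater,
                word=word,
                low_stimulus=low_id,
                high_stimulus=high_id,
                chosen=chosen,
                correct=correct,
            )
        )
    return records
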