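# Methods

## Data model and conventions

Landmark coordinates use the image convention (origin top-left, x right,
y down) in pixels. Thirteen landmark names are recognised: forehead,
throat, ears, shoulders, elbows, hands, navel, and two lectern corners.
Every downstream measure uses only distances and angles, so the convention
affects nothing but fixture construction. Frame rate is metadata only; all
kinematics are per frame, since source material of this kind rarely comes
with a trustworthy, uniform fps and conversion is a single multiplication
the caller can apply.

Manually encoded series are typically keyframed every `s`-th frame;
`interpolate_stride` restores a step-1 series by per-coordinate linear
interpolation between bracketing keyframes. Keyframes are preserved
bit-exactly (interpolated rows are computed, keyframe rows are copied), and
nothing is extrapolated beyond the last keyframe — only genuinely missing
interior frames are filled.

The motion trace is the per-frame component-wise **sum** of four landmarks
(forehead, left shoulder, both hands): one series carrying head, torso and
arm motion together. Summing rather than averaging preserves the original
analysis scale; all measures except raw distances are invariant to the
choice.

## Segmentation semantics

`segment_maxima` scans forward from the current reference point (initially
frame 0), computing the Euclidean distance from the reference to each
successive frame. A maximum is declared at frame `t` when the distance at
`t + 1` is *strictly* smaller than at `t` and the distance at `t` exceeds
`epsilon`. Ties extend the scan, so a distance plateau resolves to its last
frame; strictness makes plateaus unambiguous. The maximum's frame becomes
the new reference and scanning resumes at the following frame, so segments
chain (each unit's reference is the previous unit's maximum).

If the series ends while the running distance still exceeds `epsilon`, the
unfinished excursion is emitted as a segment ending at the final frame and
flagged `trailing=True`. It counts towards the number of maxima and the
velocity average — discarding it would systematically undercount short
clips — and the flag lets callers exclude it.

`epsilon` (default 0 px) suppresses sub-threshold jitter maxima. Hand-
encoded landmark data needs none; tracked or synthetic data with per-frame
noise can raise it (it is the documented counter-knob to the generator's
`jitter_sd`).

Distances are computed as `sqrt(dx*dx + dy*dy)` — individual IEEE
operations, not `hypot` or `pow` — so that any independent re-implementation
using the same primitive ops is bit-identical, which the test suite and the
acceptance script verify against a from-scratch re-scan.

## The four measures

* **Number of maxima**: the segment count, including a trailing segment.
* **Velocity**: per unit, peak distance over elapsed frames; per stimulus,
  the arithmetic mean over units. Undefined (reported as missing, never 0)
  when there are no units.
* **Turning angle**: direction vectors connect successive reference
  points; each consecutive pair yields the unsigned angle via the
  normalised dot product, with the cosine clamped to [−1, 1] before
  `arccos`. 0° = same heading, 180° = reversal; larger = more angular.
  Pairs containing a zero-length vector are skipped (unreachable when
  `epsilon >= 0` since every unit has positive peak distance). Undefined
  with fewer than two units.
* **Body-part angle**: per side, the angle between the shoulder segment
  (throat→shoulder) and the upper arm (shoulder→elbow), and between the
  upper arm and the forearm (elbow→hand), each as an unsigned
  chain-turning angle (0° = extended, 180° = folded back). The four angles
  are summed per frame (range [0, 720]) and averaged over frames. The
  anchoring of the shoulder angle on the throat→shoulder segment is a
  design choice; the chain-turning orientation is the only one under which
  "larger = more pointed" holds. Undefined when chain landmarks are absent.

All measures are invariant under rigid motions of the trace; distances and
velocities scale linearly with the coordinates while counts and angles are
scale-free. These invariants are property-tested.

## Statistical battery

* **Pearson correlations**: `scipy.stats.pearsonr`; two-sided t-test
  p-values; 95% CI by the Fisher z-transform with standard error
  `1/sqrt(n − 3)`. Zero-variance input is an error, not a NaN.
* **ICC**: average-measure Shrout–Fleiss forms from the two-way ANOVA mean
  squares — ICC(2,k) (two-way random, absolute agreement; the default,
  since rater panels are treated as samples from a population) and
  ICC(3,k) (consistency). CIs are the standard F-based constructions
  (direct F bounds for ICC(3,k); single-measure bounds with Satterthwaite
  degrees of freedom, Spearman–Brown stepped up, for ICC(2,k)). These are
  implemented in-package for full-precision CIs; `pingouin` serves as an
  independent oracle in the tests, which match to its printed precision.
  Degenerate perfect-agreement panels return ICC 1 with CI [1, 1].
  Average-measure ICCs have a small negative null bias of order
  `2/(n_targets − 3)`; tests of near-zero reliability account for it.
* **Subset structure**: each participant rates one stimulus subset, so
  ICCs are computed per subset (stimuli grouped by their rater set), and
  per-stimulus means are pooled across subsets before correlation.
* **Exact binomial tests**: `scipy.stats.binomtest`, one-sided (greater)
  against `p0 = 0.5` — the question is whether observers score *above*
  chance — with the conventional two-sided Clopper–Pearson 95% interval.
  Forced-choice tables are analysed overall and per word condition;
  condition counts sum to the overall counts by construction.
* **Extreme-group selection**: stimuli ranked on one measure; ties broken
  by stimulus id ascending, low tail selected first, high tail drawn from
  the remainder so the groups are always disjoint. Undefined feature
  values are excluded before ranking.
* No multiple-testing correction is applied; correlation tables carry raw
  p-values, mirroring how such rating studies are conventionally reported.

## Synthetic data

`generate_trace` plants `n_segments` motion units with amplitudes
`~N(30, 8)` px (clipped to [0.2·mean, mean + 4·sd]), durations
`~N(10, 3)` frames (minimum 2), and heading changes drawn from a folded von
Mises distribution on [0°, 180°] (default mean 150°, concentration 4) with
random turn sign. The defaults sketch a speaker gesturing over a
15-second clip: a few hundred frames, mostly pendulum-like excursions of a
few dozen pixels.

A straight-line path between unit boundaries would make any heading change
below 90° invisible to the reference-point scan (the distance from the old
reference keeps growing through a shallow turn), so units are laid down as
a *back-step and sweep*: the first frame after a boundary steps straight
back towards the previous reference (guaranteeing the strict distance
decrease that closes the unit), and the remaining frames sweep outward with
strictly increasing distance from the new reference (guaranteeing no
spurious maxima inside the unit). For turning angles near 180° this
degenerates to the natural straight out-and-back pendulum path. As a
result, with `jitter_sd = 0` the scan recovers the planted unit count
exactly, the planted per-unit velocities to floating-point accuracy, and
the planted turning angles exactly — which is what makes the generator a
usable oracle for the whole kinematic pipeline. Gaussian per-frame jitter
can be added; `epsilon` in the segmentation is the matching counter-knob.

`generate_stickfigure_series` attaches the full skeleton to a generated
trace: the rigid body translates along a quarter of the trace (so the
four-landmark aggregation sum reproduces the trace up to a constant when
the arms are still), elbows flex sinusoidally between configurable bounds,
and the lectern corners stay fixed. `static_stickfigure_series` provides
motionless postures for fixtures.

`generate_ratings` plants the feature–rating association at the stimulus
level: the stimulus mean rating is `signal_sd · (loading·z +
sqrt(1 − loading²)·e)` with `z` the z-scored feature and `e` independent
standard normals, so the expected feature/panel-mean correlation equals
`loading` exactly before rater noise; independent per-rater Gaussian noise
then attenuates the recovered correlation only by a factor involving
`noise_sd/sqrt(n_raters)` (≈1% at the defaults of 25 raters, noise 20,
signal 30). Scores are clipped to [−100, 100], the semantic-differential
scale.

`simulate_forced_choice` picks a low- and a high-feature stimulus and a
word uniformly per trial; the probability of a prediction-consistent
choice is `logistic(sensitivity · (f_high − f_low))`. Sensitivity 0 gives
chance performance, infinity a deterministic observer.

What the generator does **not** emulate: biomechanically realistic human
movement (limbs do not conserve momentum; the body is rigid), correlated
tracking error (jitter is i.i.d.), rater idiosyncrasies beyond additive
Gaussian noise (no scale-use differences, no drift), and stimulus-specific
word associations beyond a single scalar feature. Passing tests therefore
show the pipeline's arithmetic and statistics are correct and calibrated,
not that the effects would be found in any particular real dataset.

## Problem sizes and numerical choices

The test suite and acceptance script use: 1000 random traces of length
≤ 200 for the scan-vs-oracle check; 100 noise-free traces of 200 units for
parameter recovery (planted heading-change mean 60°, concentration 50);
2000 simulated binomial datasets (n = 460, p = 0.71) for CI coverage; 500
rating panels of 60 stimuli × 25 raters for loading recovery. These sizes
give Monte-Carlo error comfortably below the tolerances asserted while
keeping a full run in the order of seconds to a minute.

CSV floats are written at shortest-repr precision and parsed with pandas'
`round_trip` parser, so file round trips are bit-exact. All random state
flows from explicit integer seeds through `numpy.random.default_rng`; there
is no global random state, and identical configs give bit-identical
outputs.

## Known limitations

* The reference-point scan is sensitive to the sampling grid: resampling a
  trace changes where strict decreases occur, so stride interpolation
  should be applied consistently across stimuli before feature extraction.
* Per-frame velocity units mean cross-study comparisons require a common
  frame rate.
* The body-part angle treats each frame independently; it is a posture
  statistic, not a joint-kinematics model.
* ICC variants assume a complete rater × stimulus submatrix; planned
  missingness beyond the subset structure is not supported.
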