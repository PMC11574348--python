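# Methods

`tailbalance` post-processes two-camera markerless-tracking output from
mice crossing a narrow, tiltable ridge and asks one biomechanical
question: how much roll-plane angular momentum do tail and body rotations
generate, relative to the momentum imparted by an external tilt or by the
animal's own stepping?  This note documents the models, the conventions,
the numerical choices, and what the synthetic data generator can and
cannot establish.

## Input model and conditioning

The package consumes per-frame `(x, y, likelihood)` tables for named
bodyparts in the three-row-header CSV dialect (scorer / bodyparts /
coords) emitted by common markerless trackers, or the equivalent HDF5
layout, at 300 frames/s.  Files store image coordinates; the y axis is
flipped to y-up at the I/O boundary, so all angle math downstream assumes
math coordinates.

Samples with likelihood below the cutoff (default 0.9) are invalidated
and, by default, replaced by linear interpolation between the nearest
valid neighbours, with nearest-valid extension over edge gaps.  Whether a
tracker user interpolates, holds, or drops such samples is a genuine
choice; all three are exposed (`mode=` on `apply_likelihood_cutoff`), and
interpolation is the default because it keeps derivatives defined
everywhere, which the momentum estimates need.  A bodypart with no valid
sample at all aborts the trial with an `UnusableBodypartError` and is
logged as an exclusion at the cohort level.

All coordinate time series are smoothed with a Hanning window of 10
frames (33 ms) normalized to unit sum.  Edges are reflect-padded so the
output keeps the input length without edge attenuation; windows of 1 or 2
frames degenerate to the identity (a raised-cosine kernel that short has
no interior weight).  Angular-velocity and instantaneous-speed series are
smoothed with the same window after differentiation; for the forward
speed this is done *after* the gradient, because smoothing a steadily
advancing position trace first would flatten its slope at the trace edges
and fabricate stop episodes.

The two camera streams are aligned by cropping both to start at the first
frame where the top-view silhouette centroid is visible, and truncated to
the shorter stream.  Trial-level posture and balance metrics are computed
on the 500 samples centered in the aligned stream (odd surplus dropped
from the end); step-cycle segmentation and event-locked tilt-response
metrics use the full aligned stream, since a fixed centered window has no
privileged relation to step events or to a randomly timed tilt.

## Angle conventions

Six angles are computed per frame (degrees):

1. **Roll-plane tail angle** (rear view): the tail-base-to-first-marker
   vector measured from straight down; 0 = down, 90 = horizontal,
   180 = up, range [0, 360).  Angles in (0, 180) place the tail on the
   animal's left (the rear camera faces the animal from behind).
2. **Yaw-plane tail angle** (top view): signed angle between the
   backward ridge direction and the tail segment; 0 = straight back,
   range (−180, 180].
3. **Hip angle** (rear view): undirected hip-line angle from vertical in
   [0, 180]; 90 = horizontal.
4. **Back angle** (top view): signed angle at the tail base between the
   forward ridge direction and the base→centroid vector; 0 = hind body
   straight back along the ridge.
5. **Front angle** (top view): signed angle between the forward ridge
   direction and the centroid→nose vector; 0 = head straight ahead.
6. **Tail-on-body angle**: yaw tail angle minus back angle, wrapped to
   (−180, 180].

The "initial segment of the tail" is the tail-base marker to the first
post-base marker: the swing starts from the base, and base-segment angles
stay well defined while distal segments lag.  Angular velocity is the
central-difference gradient of the unwrapped angle scaled by the frame
rate (one-sided at the ends); unwrapping before differentiation avoids
spurious 360-degree velocity spikes when the roll angle crosses its
branch point.

Trials are labelled ipsilateral (IL) when the tilt direction matches the
side the tail is held on at tilt onset, contralateral (CL) otherwise; a
tail exactly vertical at onset is unclassifiable and the trial is flagged.
For pooling across animals that hold their tails on different sides,
angle traces are mirror-normalized to a canonical (right) tail side: the
roll angle reflects about the vertical (θ → 360 − θ) and the signed
top-view angles negate; applying the normalization twice is the identity.
Reported roll summaries use the side-normalized convention where the tail
side maps to (0, 180), so "below 90" always reads "tail below horizontal".
Raw signed angles are retained alongside.

## Step cycles

Step events are the peaks of the x-excursion of the hind paw
contralateral to the tail side, detected with a minimum separation of
half the expected stride period and a minimum prominence of 25% of the
series interquartile range (`scipy.signal.find_peaks`; the source
publication that motivated these defaults gives no peak-detection
parameters).  Detection runs on the rear-view paw x trace, which
oscillates about a stable mean; a top-view x projection would carry the
forward-progress trend.  The median inter-event interval defines the
stride period.  Epochs of any trace are cut symmetrically around each
event; the default halfwidth is one expected stride period (75 frames at
4 Hz and 300 fps), giving two-cycle windows, and is held fixed across
trials so epochs can be pooled into one correlogram.  Epochs clipped by
the trial edges are excluded, exactly.  Per-epoch statistics are the mean
(cycle position) and max − min (cycle range); trial values average over
epochs, and group statistics average trials within animal first.

## Balance metrics

All five metrics derive from the top-view centroid, with the ridge along
+x and the midline at lateral offset 0, scaled by the per-view
mm-per-pixel calibration (obtainable from the known 500 mm ridge length):

- **traversing speed**: endpoint forward displacement over elapsed time
  between first and last visible frame; also reported with stop time
  excluded from the denominator, since the two conventions answer
  different questions and the choice is not otherwise fixed;
- **stops**: maximal runs of instantaneous forward speed below 1 mm/s
  (the immobility threshold);
- **time outside the base of support**: total time with |lateral offset|
  strictly greater than half the ridge width — a centroid exactly on the
  edge is inside;
- **lateral movement**: mean absolute lateral offset (mm) over visible
  frames;
- **centrality**: mean of 1 − |offset|/(width/2), clipped at 0 beyond the
  edge, so 1 = midline, 0 = edge.

Slip counts are manual labels merged from an optional table, never
computed from video.  The ridge midline comes from trial geometry, not a
fit.

## Biomechanical model

Angular momentum is L(t) = I·ω(t).  The tail is a uniform rod of length
l = 7 cm and mass 0.5 g rotating about its base, I = (1/3)·m·l²
(a center-axis switch, (1/12)·m·l², is provided; the base axis is the
default because the swing visibly starts at the tail base).  The body is
a solid cylinder of radius 1 cm and mass 20 g about its long axis,
I = (1/2)·m·r².  Tail ω comes from the roll-plane tail angle, body ω
from the hip angle, both converted to rad/s.

The momentum imparted by the tilting platform is the model's weakest
joint: the animal sits at the edge of a rotating platform, and what
"radius" to use is genuinely ambiguous at this level of abstraction.
Three variants are implemented and the choice is recorded in the output:

- `cylinder_platform_radius`: I = (1/2)·M·r_p² with r_p the ridge
  half-width — with a millimetre-scale half-width this makes the
  perturbation momentum implausibly small against the tail's;
- `point_mass_at_edge`: I = M·d²;
- `cylinder_plus_parallel_axis` (default): I = (1/2)·M·r_b² + M·d² with
  d = r_b, i.e. the body cylinder displaced one body radius from the
  rotation axis,

with M the total mass.  The platform's angular speed is
amplitude/duration during the ramp (piecewise constant) and zero after —
the ridge stays tilted.

Window totals are trapezoidal time integrals, signed by default (an
absolute mode exists); signed totals make out-and-back rotations cancel,
which is the physically meaningful bookkeeping for net compensation.
Early/late response phases split at the end of the tilt ramp, with the
response window defaulting to 0.5 s after onset.  Compensation fractions
are totals divided by the *opposing* platform total, so a counteracting
response is a positive fraction and full cancellation is 1.

## Tail–body coupling

For each ridge width, step-cycle epochs of tail and body momentum from
unperturbed trials are pooled and correlated *across epochs*: cell (i, j)
of the correlogram is the Pearson correlation, over epochs, of tail
momentum at cycle time i against body momentum at cycle time j.  (The
alternative reading — within-trial lagged correlation — is available via
`mode="within_trial_lag"`.)  Zero-variance bins yield undefined cells
that are excluded from the percentile pool.  Hotspots and coldspots are
the largest 8-connected components of cells in the upper and lower 5%
tails of the defined-cell distribution, with ties broken by larger
absolute mean correlation.  The matrix diagonal is the zero-lag coupling
through the cycle; momenta enter in the lab frame, whose correlations are
mirror-invariant, so left- and right-tailed trials pool without sign
fixing.

## Statistics

Group comparisons use a classic one-way ANOVA (between/within sum of
squares) on per-animal means, Bonferroni-adjusted pairwise pooled-variance
t-tests (p multiplied by the number of comparisons, capped at 1,
significance at 0.05), and mean ± s.e.m. summaries.  Tail probabilities
come from the regularized incomplete beta function.  A Welch option
exists for unequal variances.  Degenerate cases (zero within-group
variance) are flagged rather than silently returning infinities as
significant.

## Synthetic data generator

No public recordings accompany the behavioural study this pipeline is
built for, so the generator produces two-view keypoint tables with known
ground truth that emulate the *statistical structure* the analysis
assumes:

- step-locked sinusoidal paw, hip and tail oscillations at 4 Hz, tail
  anti-phase to the hips by default;
- a side-held tail whose mean roll angle and oscillation amplitude depend
  on ridge width (narrower ridges: tail lower — below horizontal at
  ≤ 5 mm — and swung over a larger range);
- on tilt trials, a minimum-jerk tail swing to the opposite side
  (bell-shaped velocity; amplitude fixed by the configured peak speed of
  2.2 rotations/s and peak-position time of 0.16 s, followed by a partial
  return) and a smaller out-and-back hip deflection peaking at 0.12 s;
- stepping and forward progress gated off smoothly around the tilt,
  mirroring the stopping behaviour large tilts evoke — without the gate
  the stride oscillation would alias into the swing and the configured
  peak speed would not be a well-defined ground truth;
- forward centroid progress at 150 mm/s with smooth lateral wander
  (1 mm s.d.) and a small step-locked sway;
- Gaussian pixel noise (1 px s.d., typical tracker jitter) and random
  likelihood dropouts (2%) whose coordinates are displaced, exercising
  the conditioning path.

Calibrations default to 0.25 mm/px (rear) and 0.5 mm/px (top), plausible
for high-speed cameras at the described working distances.  Right-tailed
trials are full mirror images of left-tailed ones (roll, hip, tilt
direction all mirrored together).  Cohorts add per-animal multiplicative
Gaussian jitter (3% s.d.) to amplitudes and speeds, rotate condition
order per animal, and randomize tilt onset within the trial.  Everything
is deterministic given the seed.

What the generator does **not** emulate: tracking failures correlated
with posture, camera lens distortion, tail-ridge contact (which truncates
contralateral swings in real data), slip biomechanics, and any
neural/behavioural variability beyond parameter jitter.  Passing
recovery tests therefore shows the *pipeline* is unbiased under the
stated noise model, not that the biological estimates in any particular
dataset are correct.

## Numerical choices and degenerate inputs

- Hanning smoothing attenuates the swing's peak angular velocity by
  ≈ 2% at the default window; recovery tests bound the total pipeline
  bias at 3% over 20 trials.
- Window integrals resample the trapezoid exactly at the window edges so
  adjacent windows add exactly.
- Coincident keypoints raise `UndefinedAngleError`; empty silhouette
  masks map to non-visible frames; empty epochs/peak sets are warnings
  plus logged exclusions (`no-steps`, `too-short`,
  `unclassifiable-laterality`, `unusable-bodypart`, `missing-file`),
  never silent drops.
- Percentile thresholds use all defined correlogram cells; `>=`/`<=`
  comparisons keep threshold-valued cells.

## Problem sizes

The test suite and the acceptance script use 3 s trials (900 frames) at
300 fps; recovery statistics average 20 seeded trials; the end-to-end
check runs a 15-animal × 4-width × 2-trial-type cohort (120 trials).
These sizes give stable means (s.e.m. of the recovered peak speed ≈ 0.01
rotations/s) while keeping a full run to seconds.

## Known limitations

The model ignores ground-reaction forces and limb torques; momenta are
planar (roll only); the perturbation inertia is a modelling choice (see
variants above); hip-angle-based body ω treats the hip line as rigid with
the trunk; and the correlogram's across-trials reading assumes epochs are
exchangeable within a width.
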