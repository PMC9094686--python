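# Methods notes

This note records the models, conventions and numerical choices behind
`vrbat`, in the spirit of a statistical software appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate and timing conventions

Positions are in meters in a right-handed frame with `y` up: `x` spans the
4.6 m field width, `z` the 4.3 m depth, origin at the midpoint of the long
side where the participant starts. This makes *side membership* — which
half of the field the pelvis occupies — a sign test on `x`. Yaw is in
degrees, 0 = facing `+z`, counter-clockwise viewed from above, so the
forward vector is `(−sin ψ, cos ψ)` in the horizontal plane. All streams
and events share one clock in seconds from session start; the analysis
windows (10 s wait, 120 s search, 0.5 s and 1 s pre-touch) are then plain
interval arithmetic.

The participant's position is the **pelvis** sensor throughout (distances,
side occupancy, passage classification, thirds). Side occupancy is defined
on the pelvic half, and using a single body point everywhere avoids
disagreement between sensors. Orientation angles also use pelvis yaw; the
body segment is configurable in principle (hip vs chest conventions differ
between labs) but the pelvis is the default.

## Task readouts

*Search task.* Minimum horizontal pelvis–stimulus distance over the 120 s
window beginning at the end of the 10 s wait; readout = spider minimum −
turtle minimum. The orientation angle is `arccos` of the normalized dot
product between the forward vector and the horizontal pelvis→stimulus
vector, averaged over the samples spent on that stimulus' half; a
participant who never enters the spider half yields a missing angle and an
exclusion flag rather than an imputed value.

*Forced-choice task.* Passage side is decided at the **first crossing** of
the gate line (the central table's z-midline); later re-crossings within a
leg do not reclassify, since each leg has one decisive passage. A trial's
outward/return legs are split at the moment of deepest penetration (the
book pickup). The weight table — book centered: both sides 1; slightly
offset: near side 0, far side 2; far offset: near side 0, far side 4 — is
the unique assignment under which the all-avoid and never-avoid policies
reach exactly ±14 under the side-swap schedule (swap after trials 1 and 3).
Contributions are signed **positive when the chosen side is not the
spider's**, anchoring the score's sign to "+14 = always avoided the
spider"; the opposite convention is available via `spider_positive=False`.

*Approach task.* Time to touch = stimulus-touch event − countdown-end
event. The readout (first spider − first turtle trial) is truncated at
20 s from above only; faster spider touches stay negative and untruncated.
The "thirds" split the start→table axis into three **equal-length
projection bands** (an equal-floor-area split would be an alternative; the
distance bands match the proximity interpretation). Acceleration sign
changes use the second central difference of the 10 Hz spline-resampled
hand track, counted per coordinate axis with zeros ignored and summed over
axes; counting on a magnitude signal or a principal axis would be
defensible alternatives, but the per-axis sum is the simplest
total-variation-like count. Magnitudes below 1e-9 of the position scale
count as zero so exactly straight segments are immune to rounding noise.

## Signal preprocessing

*Pupil.* Outliers are samples more than k = 3 **scaled MADs**
(1.4826 × median absolute deviation, the normal-consistency constant) from
the moving median of a centered 100-sample window, shrunk at the edges.
Zero-MAD windows flag nothing (strict inequality), so constant stretches
are never self-flagged. Closed eyes are simply invalid samples; there is
no separate velocity-based blink detector. Missing runs are linearly
interpolated in time (edges take the nearest valid value), the series is
resampled to 110 Hz by nearest neighbour, and min–max rescaled to [0, 1].
A constant series rescales to all zeros (documented degenerate rule).
Rescaling is **per task segment** by default so that a task's dynamic
range is not dominated by illumination differences between scenes.

*Glances.* The focus label is treated as a step function holding from each
sample to the next; maximal runs on the target become intervals, and
interruptions strictly shorter than 200 ms merge. Merging is idempotent.

*RR.* The beat series is rendered as a 250 Hz step function (each RR value
holds from its beat until the next) and windowed means average the rendered
samples; this matches the storage convention of the upstream RR pipeline
rather than beat-weighted averaging. Windows containing no rendered sample
yield a missing value plus an exclusion flag, never zero.

## Statistics

The mixed repeated-measures ANOVA projects each subject's within-cell
vector onto orthonormal Helmert contrasts per within-effect stratum and
runs a one-way between-groups decomposition on the projections. Hypothesis
sums of squares are **Type III with sum-to-zero contrasts** (unweighted
group means), the common default of commercial packages; with unbalanced
groups the Type III within-effect SS therefore differs from the weighted
(sequential) grand-mean SS, and the exact stratum decomposition is kept on
the result object (`stratum_totals`, `stratum_decomp`) so the complete
partition of the total SS can always be verified. Effect sizes:
ηp² = SS/(SS + SS_error-of-that-effect); η²G = SS/(SS + Σ all error SS),
which never exceeds ηp² and equals it exactly when the design has a single
error term. Effects with zero SS report F = 0, p = 1.

Mann–Whitney U is counted as Σ(aᵢ > bⱼ) + ½ ties and reported with the
max(U, n₁n₂ − U) convention; p values are exact for tie-free samples with
n₁n₂ ≤ 400, otherwise tie- and continuity-corrected normal. **Cohen's U3
is the proportion of the first sample's values strictly below the median
of the second (reference) sample, ties counted half**: a group lying
entirely above its reference has U3 = 0. Effect-size toolboxes differ in
this direction; the convention here makes small U3 mean strong separation
of the first group above the reference, which is how the published values
this package emulates behave. Glass' Δ standardizes by the second
(reference) sample's SD and is flagged undefined when that SD is zero.
Hedges' g₁ uses the exact gamma-function small-sample correction. Partial
Spearman is the first-order recursion on tie-averaged ranks with a t
approximation on n − 3 degrees of freedom.

## The synthetic cohort

One latent scalar — spider aversion — drives every modality through
per-modality gains, mirroring the empirical pattern that trait spider fear
dominates all readouts and keeping parameter-recovery tests
one-dimensional. Group structure: 15 phobic, 6 fearful, 10 non-fearful;
aversion ~ N(2.0, 0.4), N(1.0, 0.4), N(0.0, 0.4) respectively. FSQ totals
are integers drawn per group (0–8 / 9–40 / 60–108), rank-matched to the
latent aversion, honoring the cutoff-8 partition.

Generated signals: a bounded drift walk at a 0.2 s decision step (repulsion
from the spider plank ∝ aversion/distance, exploration waypoints resampled
inside an aversion-scaled avoidance radius), glance renewal with a
spider-hazard gain, yaw biased toward the spider on its half, logistic
passage choices with utility −cost − β·aversion·[spider side] (β = 2.5),
approach walks with hesitation ∝ aversion concentrated in the last third
(slowdown factor 1 + 3·h·p⁴) plus everyday distraction pauses and reaction
times, a hand tremor whose frequency grows with aversion (so the 10 Hz
sign-change count grades with fear and saturates past the cap only at high
aversion), pre-touch pupil dilation ramps, and RR shortened on the spider
half and before spider touches. The **habituation factor** (default 0.4)
multiplicatively reduces effective aversion on the second spider exposure,
i.e. hesitation drops to 60 % of the first trial. Streams are emitted at
90 Hz (motion), ~110 Hz with frame jitter (gaze), and as beat events (RR);
generation is fully deterministic given the seed.

With default gains the phobic vs non-fearful contrasts land at large
standardized effects (Glass Δ roughly 2–4 across the three readouts) and
strong FSQ rank correlations — the *direction and order* of effects seen
in real phobic cohorts. The generator makes no claim to biomechanical
realism: no gait dynamics, no illumination-driven pupil changes, no head-
motion artifacts, no questionnaire item structure (scale totals only).
Passing recovery tests therefore shows the pipeline recovers effects of
this structure and size, not that it would behave identically on real
recordings, where pupil illuminance confounds and movement-driven heart-
rate changes are substantial.

## Test problem sizes

The suite verifies oracle equivalence on 1,000 random glance sequences,
500 Mann–Whitney draws, and 100 smooth-plus-jitter trajectories; ANOVA
internal consistency on 200 random mixed designs; type-I calibration on
1,000 reduced-size null cohorts (5/4/5) at α = 0.05 with a ≤ 7 % rejection
bound, and on 5,000 pure-statistics null simulations; and parameter
recovery on 100 full default cohorts (≥ 90 % detection of the phobic vs
non-fearful contrast per readout, median readout–FSQ Spearman ≥ 0.5).
Readout-row invariants are checked across two full generated cohorts;
these sizes keep the default test run in a few minutes while bounding
Monte-Carlo error well below the asserted margins.

## Known limitations

* The mixed ANOVA requires complete within cells; subjects with missing
  cells are dropped from that analysis (and logged), not imputed.
* Exact Mann–Whitney p values are not available under ties; the corrected
  normal approximation is used instead.
* RR streams are consumed as validated beat series; R-peak detection from
  raw ECG is out of scope, as is eye-tracker calibration.
* Partial correlations are first-order only; no mediation model is fitted.
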