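# Methods

This note documents the models and procedures implemented in `liftforce`,
the parameters that matter, and what the synthetic cohort does and does not
establish about real recordings.

## Experimental design

A session is a sequence of lifts of a light (125 g) and a heavy (518 g)
cube, both 6 × 6 × 6 cm (216 cm³; densities 0.58 and 2.40 g/cm³). The
scientific questions concern *ordered transitions* — whether a lift repeats
the previous weight (no-switch) or changes it (switch) — so the sequence
must contain each of the four ordered pairs equally often. Rather than
rejection-sampling shuffles (the probability that a random 81-lift shuffle
is exactly balanced is negligible), `design.generate_balanced_sequence`
builds the 2-node multigraph whose edges are the required transitions
(n parallel edges per ordered pair) and emits a randomized Hierholzer
Eulerian circuit; in- and out-degrees are balanced by construction, so a
circuit always exists, and its node-visitation order is the sequence. The
circuit's start node is uniform per seed. A sequence of 4n + 1 lifts yields
exactly n analyzable trials per (cube, switch) cell after the first lift —
which has no predecessor — is discarded. No maximum-run-length constraint
is imposed by default; an optional post-hoc cap is available for users who
want one.

## The lifting simulator

Each trial simulates 4 s at 400 Hz. All forces are in newtons internally;
masses enter in grams and are converted once with g = 9.81 m/s².

**Programmed lift.** After a quiet `reaction_time` (0.3 s), the total load
force follows a minimum-jerk ramp from 0 to `overshoot × expected
weight-force` over `rise_time`:  f(t) = F_target (10s³ − 15s⁴ + 6s⁵),
s = t/T. The minimum-jerk profile is the standard model of programmed
motor output in the lifting literature, and its defining property drives
everything downstream: its rate peaks exactly at the temporal midpoint.
If the target plateau is below the object's weight-force (an
underestimated weight), a linear feedback correction at `correction_rate`
continues until the weight is exceeded. Lift-off is the first sample at
which total load force reaches the weight-force; the photogate flips
there, and the trial is flagged (never raised) if lift-off does not occur
within the trial window.

**Channels.** The handle records half the total load force (the thumb side
is unmeasured, as in the standard apparatus); grip force is `grip_ratio ×`
total load force; the platform reads `max(0, weight − total load)`,
clamped to zero from lift-off onward — the platform's defining truncation.
Independent Gaussian noise (`noise_sd`, per channel, per sample) is added
last.

**Expectation.** The expected mass follows an exponential memory
E_t = λ·mass_{t−1} + (1 − λ)·E_{t−1} with λ = 1 by default (a pure
one-trial-back expectation, the minimal model that produces switch
effects); E_1 is the mean of the two masses. With `overshoot` α and a
light object following a heavy one, α·E ≫ weight, the weight-force
crossing falls before the ramp midpoint and the platform truncates the
rate peak; a correctly anticipated lift (α = 1.1) crosses at
s ≈ 0.79 > 0.5 and the platform records the full peak. This is the
mechanism under study, and it emerges from the force model rather than
being scripted.

**Ratings.** Perceived heaviness is
`scale × actual × (1 + β (actual − expected)/actual) × exp(ε)`,
ε ~ N(0, `rating_noise_sd`), floored at a small positive constant.
The multiplicative log-normal noise and the log-normal per-participant
`scale` (sd `scale_spread` = 0.8 on the log) mimic free-scale magnitude
estimation, whose %-score normalization is scale-free.

**Heterogeneity.** Per-participant log-normal jitters (sd
`participant_sd` = 0.15) multiply rise time, grip ratio, overshoot and
correction rate; per-trial jitters (sd `trial_jitter_sd` = 0.05) multiply
rise time, overshoot and correction rate. These produce the between- and
within-participant variance the ANOVA and ICC require. The overshoot and
correction-rate jitters matter most: participant-specific overshoot makes
the truncation point — and hence the platform's distortion of the
force-rate peak — vary across participants, which is what degrades
handle-platform agreement specifically in the light-after-heavy cell.

**Default behavioural parameters** (chosen once on domain grounds, not
stated by the study conditions): α = 1.1 (slight habitual overshoot,
guaranteeing lift-off on the programmed ramp when the weight is
anticipated), rise_time = 0.5 s (typical load-phase ramps of a few hundred
milliseconds), correction_rate = 8 N/s (a feedback correction distinctly
slower than a programmed heavy lift's ~21 N/s peak rate), grip_ratio = 1.5
(grip ≈ 1.5 × load, a typical safety margin over the slip ratio),
noise_sd = 0.02 N (six-axis transducer noise floor), β = 0.03 (yields
switch effects of a few percent in the %-scores, the size such contrast
effects take empirically), rating_noise_sd = 0.1.

**Seeding.** One global seed fans out through
`numpy.random.SeedSequence.spawn`, one independent child stream per
participant; each participant's balanced sequence is generated from a seed
drawn from their own stream. Consequently runs are bit-reproducible and
adding participants never perturbs earlier participants' data.

## Trace processing and measures

Force channels are smoothed with a fourth-order zero-phase (forward–
backward) low-pass Butterworth filter at 14 Hz before differentiation and
all event detection. The forward–backward pass squares the magnitude
response — attenuation of a tone at f Hz is 1/(1 + (f/14)^8) — and has
exactly zero phase lag, so event times are not shifted. Rates are
three-point central differences ((x_{i+1} − x_{i−1})·fs/2), with one-sided
differences at the two boundary samples so outputs keep the input length
(exact for polynomials of degree ≤ 2 on the interior).

The handle onset is the first sample at which the doubled handle load
strictly exceeds 0.2 N; the platform onset is the first sample at which
the platform's force *reduction* (resting baseline — the median of the
filtered channel over the initial 0.2 s — minus the reading) strictly
exceeds 0.4 N (the platform sees full force, not half). Lift-off comes
from the photogate. Thresholds are applied to filtered signals.

Windows respect what each instrument can record: handle peaks (PLF, PLFR,
PGF, PGFR) are global maxima over [handle onset, trace end]; platform
measures stop at lift-off (PPFR over [platform onset, lift-off];
LPD2 = lift-off − platform onset; LPD1 = lift-off − handle onset).
First-peak measures replace the human rater of traditional workflows with
a prominence criterion: the first local maximum of the rate series whose
prominence is at least `min_prominence` (default 0.05) of the window
maximum; LF1st and PF1st are the load / reduction values at that time.
A monotonically rising rate — the truncation case — has no qualifying
peak, and the measure is recorded as absent *with a reason*, never
silently. LF1st is searched over the full handle window (the handle keeps
recording through the hold phase, so the first peak is identifiable even
when it falls just after lift-off), whereas PF1st cannot see past
lift-off; this asymmetry is precisely what makes PF1st fragile for light
objects.

Two numerical choices deserve note. First, the platform channel is
truncated at lift-off *before* filtering: a zero-phase filter applied to
the full channel would smear the post-lift-off plateau backwards in time
and fabricate a pre-lift-off rate peak the instrument never recorded.
Second, a first-rate-peak landing within one filter time constant
(1/cutoff ≈ 71 ms) of a recording boundary is indistinguishable from the
filter's edge transient, so the first-peak search window ends that far
before the boundary (`edge_guard`, default 1/cutoff).

Magnitude estimates are normalized per participant to %-scores,
(estimate − mean)/mean × 100, over that participant's analyzable trials.
The published verbal description of the normalization has the opposite
sign, which would make heavier-felt objects score negative and contradict
the way such results are reported; the package defaults to the
positive-heavier convention and offers the literal sign behind
`literal_percent_sign`.

Outliers are removed per variable where |value − mean| > 3 SD (n − 1
denominator), mean and SD computed in a single pass on the full group, no
re-iteration; a zero-SD group retains everything. The grouping level is
participant × measure × cube (pooling switch levels), which removes
trace-level artifacts without erasing switch effects; alternatives are one
config switch away.

## Inferential layer

All sums of squares are computed in-package (pingouin and a
statsmodels-assembled two-way ANOVA serve only as independent oracles in
the test suite).

**ICC(3,1).** Agreement between the two fixed instruments is the two-way
mixed-effects, single-measure, *consistency* intraclass correlation: with
row (subject) mean square MS_R, column (method) mean square MS_C and
residual MS_E from the two-way decomposition of the n × 2 table,
ICC = (MS_R − MS_E)/(MS_R + (k−1) MS_E), k = 2. The consistency form is
the right one for fixed methods whose additive offset is irrelevant;
absolute agreement ICC(A,1) is available behind a flag for sensitivity
analysis. 95% confidence limits use the exact F bounds on MS_R/MS_E
(Satterthwaite-approximated F limits for the absolute form). Rows with any
missing value are dropped pairwise, mirroring how only recorded values can
be compared; fewer than 5 complete pairs is reported as insufficient data,
and zero total variance as undefined. Estimates are binned into poor
(<.50), moderate (.50–.75), good (.75–.90) and excellent (>.90); because
the conventional ranges share their endpoints, a boundary value falls in
the lower-named band by default (.75 → moderate), with the upper
convention one flag away.

**2 × 2 repeated-measures ANOVA.** Per-participant cell means feed a fully
within-subject decomposition; each effect (cube, switch, interaction) is
tested against its own subject-interaction error term with df = (1, n−1).
With two-level factors each effect is an orthogonal within-subject
contrast, so F = t² identically and sphericity holds trivially (no
correction is applicable). Partial η² = SS_effect/(SS_effect + SS_error).
Zero error variance yields an explicitly degenerate result rather than an
exception. Post hoc, the two contrasts of interest — switch vs no-switch
within each cube — are paired t-tests with Bonferroni correction over the
family of 2 and Cohen's d. The d standardizer is d_z (mean difference over
the SD of the differences) by default, with d_av (mean difference over the
average condition SD) available; reports always name the variant, because
the two can differ severalfold on strongly correlated within-subject data.

**Null calibration.** On pure-noise cohorts the interaction test's
rejection rate at α = .05 sits within binomial tolerance of 5%
(the acceptance suite checks [3%, 7%] over 1,000 simulated null cohorts of
29 participants).

## Problem sizes

The end-to-end checks use the full default cohort — 29 participants × 81
lifts = 2,349 trials of 1,600 samples × 4 channels — which simulates and
analyzes in a few seconds; the null calibration uses 1,000 cohorts of
29 × 4 cell means. Property tests run at small n with brute-force oracles.

## What the synthetic cohort shows — and does not

Passing tests establish that the implementation reproduces the *mechanism*:
with a one-back expectation and β > 0, perception, PPFR and LPD2 show the
expected interaction directions; PF1st is absent far more often for light
than heavy objects; and handle-platform ICC is high for heavy-after-heavy
but substantially lower for light-after-heavy — the qualitative ordering
reported for real cohorts. The simulator is not a behavioural digital
twin: it omits vertical kinematics (only forces are modeled), set-down
forces, torques and 3-axis decomposition, lid dynamics of any particular
platform build, and trial-to-trial strategy changes beyond log-normal
jitter; its effect *magnitudes* are therefore not calibrated to any
empirical dataset, and analyses of real recordings should treat the
defaults as a starting point, not ground truth. The automated first-peak
detector is also deliberately simple: at low force-rate scales (light
objects) its 5% prominence criterion admits noise-induced local maxima
that a human rater would ignore, which lowers first-peak agreement between
instruments relative to rater-based workflows.

## Known limitations

* The expectation model is first-order (λ-exponential); slower adaptation
  or Bayesian pooling over the session is not modeled.
* Lift-off is defined purely by the force balance; real photogates can
  trigger on tilt or partial unloading.
* The literal-sign %-score variant and absolute-agreement ICC exist as
  flags but the pipeline reports only the defaults.
* Imported real data must already be expressed in the trace schema (time,
  grip, load, platform, photogate at uniform sampling); no resampling or
  gap repair is provided.
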