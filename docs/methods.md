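# Methods

This note documents the models, estimators, parameters and numerical
choices behind each metric, what the synthetic generator does and does not
emulate, and the known limitations.

## Input model

All metrics operate on two inputs. A **landmark series** is an ordered
sequence of frames, each holding named 2D points in pixels with a detection
confidence in [0, 1]; names come from a fixed registry (`LANDMARK_REGISTRY`)
so the core is independent of any particular detector — an adapter maps a
detector's output onto the registry. Image convention: origin top-left,
y increases downward; every "vertical opening" is defined as lower-point y
minus upper-point y ≥ 0. A **transcript** is an ordered list of words with
start/end times; milliseconds (the common ASR convention) are converted to
seconds at read time when timestamps are integral and exceed 1000.

Typical recordings run at 25 fps (occasionally 30); quality control rejects
other rates, unstable frame gaps (> 5% of inter-frame gaps deviating more
than 50% from the nominal period), insufficient landmark coverage of the
exercise's region of interest (any required landmark confidently present in
under 90% of frames), and eyes imaged at under 7 px of lid aperture —
operating on landmarks rather than raw video, "too close to camera" and
"poor illumination" are proxied by missing or low-confidence landmarks.

## Filtering

Landmark traces carry frame-to-frame detector jitter and occasional
single-frame failures (blinks, occlusions). The standard filter is a moving
median followed by a moving average, both over the same window
(`ptosis.window_s`, default 0.5 s), centered, with shrunken windows at the
endpoints so output length equals input length. The median removes isolated
spikes exactly; the average suppresses residual jitter. Two deliberate
exceptions:

- **Hold-time detection** (arm endurance) uses the moving median alone.
  The averaging stage turns an abrupt drop into a ramp whose
  threshold crossing is biased early whenever the threshold is not midway
  between the two levels (here: 60° between ~80° and ~20°, a ~0.1 s bias).
  The median preserves the step edge, keeping the crossing within two frame
  periods of the true drop.
- **Lip acceleration** applies no pre-smoothing by default
  (`mouth.window_s` = 0). Articulation during counting lives at a few Hz;
  a 0.3–0.5 s moving average attenuates a 2 Hz component by roughly half
  and would corrupt the acceleration magnitude far more than the jitter it
  removes over the short counting window. The option remains available for
  unusually noisy input.

## Ptosis

The palpebral aperture is filtered and summarized as
`retained_pct = 100 · Q_q / Q_{1−q}` with q = `ptosis.robust_q` (0.05).
Both extremes are robust quantiles: a residual blink cannot set the
minimum, and — equally important under two-sided jitter — the raw maximum
of ~1500 filtered samples is upward-biased by extreme-value statistics,
which would systematically deflate the score by ~1–2 points; the symmetric
quantile removes that bias. The score is a ratio of pixel lengths and hence
exactly invariant to camera distance, which varied several-fold in
practice.

Pattern classification: `stable` if the filtered change (100 − retained)
is within `ptosis.noise_pct` (4%, the filtered variation bound observed in
controls under 70); otherwise `linear_fatigue` if the OLS line on the
filtered aperture has negative slope and R² ≥ `ptosis.r2_min` (0.6);
otherwise `unstable`. R² is defined as 1 − SS_res/SS_tot clipped to [0, 1],
with the convention that a zero-variance series fits its own mean exactly
(R² = 1) — classification never reaches that branch because such series are
`stable` first.

Head-tilt compensation is flagged when the filtered chin-to-crown vertical
extent shows a trend (linear fit, R² ≥ 0.5) whose total relative change
exceeds `ptosis.head_tilt_rel_change` (0.15) of the initial 2-s median;
missing head landmarks yield an indeterminate (None), distinct from False.

## Ocular alignment

Per eye, the barycentric iris coordinate is
b = (x_iris − x_inner)/(x_outer − x_inner) with signed differences, clamped
to [0, 1]; widths under 3 px raise a resolution error. Mirroring the left
eye (b ← 1 − b) puts both eyes on a common axis in image space, so
conjugate gaze — the normal, yoked wandering of both eyes — cancels exactly
in m = b_L − b_R, and 0 means aligned at any gaze direction. The summary
`drift_total` is the OLS slope of m times the exercise duration.
|drift_total| below `alignment.floor` (0.05) is reported but flagged
indeterminate: consumer video cannot resolve smaller misalignments, and
flagging below instrument resolution would manufacture false positives.
Sessions whose iris excursion is predominantly vertical with no horizontal
signal are likewise indeterminate; vertical misalignment is out of scope.
Diplopia reports are timestamped by case-insensitive keyword/phrase
matching over adjacent transcript words (defaults: "double", "two of",
"diplopia", "split").

## Arm endurance

θ(t) is the angle between shoulder→wrist and the torso axis
(mid-shoulder→mid-hip), computed with atan2(|cross|, dot) ∈ [0, π] — exact
under translation, uniform scaling and global rotation. The exercise starts
at the first sample with θ ≥ `arm.start_angle_deg` (70°); it fails when the
median-filtered θ stays below `arm.fail_angle_deg` (60°) for
≥ `arm.sustain_s` (1 s), so a momentary dip does not end the hold; hold
time is capped at `arm.cap_s` (120 s). The abduction posture is nominally
90°; the 70/60 pair gives an explicit, configurable start/failure
criterion. Drift is the OLS slope over the held window × hold time, in
radians over the test so it is directly comparable across sessions
(negative = downward); the raw slope is also reported. Patterns:
`abrupt_drop` when the hold ended early and the final 1-s mean angle sits
> `arm.abrupt_drop_rad` (0.3 rad) below the fitted line's extrapolation —
the sudden simultaneous loss of force, as distinct from gradual fiber
drop-out; `drift` when the drift is flagged abnormal; else `sustained`.
A hip-stability proxy (hip-y range > 25% of trunk length) marks sessions
where the seated requirement was violated as indeterminate.

## Sit-to-stand

The mid-hip height (−y) is lightly median+mean filtered (`sts.window_s`,
0.12 s — short, because the ascent itself can be under a second), and its
time derivative taken by central differences. The **ascending phase** is
defined as the maximal interval around the velocity peak where upward
velocity exceeds `sts.velocity_frac` (10%) of the peak; its length is the
ascending time. The synthetic generator parameterizes its logistic rise by
exactly this span (7.274 logistic time constants), so the generator's
`true_ascend_s` and the detector measure the same quantity by construction;
for other rise shapes the 10%-velocity span is simply what the metric
means. Standing is achieved when the total hip rise reaches
`sts.min_rise_frac` (50%) of the trunk length (mid-shoulder to mid-hip), a
displacement scale available without camera calibration. Missing head-top
coverage sets `partial_view` without invalidating the timing.

## Counting speech

Parsing recognizes digits 1–50, simple number words, adjacent-word and
hyphenated compounds ("twenty one", "twenty-one"; the compound takes the
first word's start and the last word's end), and the counting homophones
to/too → 2, for → 4, ate → 8, won → 1 — accepted only when an adjacent
transcript word is itself a number, so ordinary prose ("thanks for coming")
is not miscounted. Segment location finds the run of strictly increasing
values starting at ≤ 2 that accepts the most tokens, where each skipped
interleaved token and each missing value consumes one unit of a budget of
`speech.max_skips` (3). The search is an exact memoized recursion with a
canonical tie-break (most tokens, then lexicographically earliest indices);
transcripts are a few hundred words at most, so exactness costs nothing.
Runs shorter than `speech.min_run` (5) raise a segment-not-found error.

Breath pauses are inter-token gaps measured **end → start** (articulation
time excluded) exceeding `speech.pause_gap_s` (1.0 s) — above the observed
0.5–1.5 s onset-interval range precisely because onset intervals include
the spoken word. The single-breath count is the value of the last token
before the first pause (overall maximum if none); counting time runs from
the first token's start to that token's end. The counting pace is not
standardized by the exam, so no normative flag attaches to the mean
interval. A corollary of the gap definition: a number lost by the
recognizer leaves a silence indistinguishable from a breath pause, so
breath metrics are only as reliable as the transcript is complete.

## Lip acceleration

u(t) = upper-lip y ÷ mouth width (|x_right − x_left|; frames under 3 px are
dropped and counted). Width normalization makes the metric camera-distance
invariant and robust to head pitch; inter-ocular distance is available as
an alternative normalizer. The second derivative uses the 3-point central
stencil at the native frame period; the stencil annihilates constant and
linear terms, so slow head drift does not contaminate the result. The
summary is the mean of |u''| over the located counting segment (silence
would dilute a whole-recording average); the standard deviation of u'' is
exposed as an option. For u = A sin(2πft) the expected value is
A(2πf)²·(2/π), with the discrete stencil under-reading by the factor
sinc²(πf/fs) (~2% at 2 Hz, 25 fps).

## Normative thresholds

Per metric and age stratum, the threshold is control mean ± 1 sample SD
(n − 1 denominator, appropriate for small control panels), on the side that
is abnormal for that metric: retention and lip acceleration low, alignment
drift and ascent time high, arm drift negative. The age cut is strictly
greater than 70 years. Values exactly on the threshold are normal. Under a
normal control model the expected abnormal rate among fresh controls is
Φ(−1) ≈ 15.9% — the rule trades specificity for a continuous, transparent
criterion. Shipped defaults are tagged `paper-implied`: arm drift
mean −0.05 / threshold −0.12 (≤ 70) and −0.15 / −0.24 (> 70), whose SDs
(0.07, 0.09) are implied rather than published, and a ptosis retention
floor of 96% encoded as mean 100, SD 4 from the control variation bound.
The arm-drift flag applies to drift *more* negative than the threshold,
consistent with the threshold's construction as control mean − 1 SD
(prose statements of such rules sometimes invert the comparison; the
construction is authoritative here). Sites should replace the shipped norms with
`compute_normative` on their own control table (`mgce norms`).

## Synthetic exams

The generator emulates the phenomenology each metric must resolve, on a
fixed canonical face/body template with an optional camera-scale factor
(exercising the scale-invariance claims): linear lid droop with opening and
floor plateaus (so the robust quantiles of the filtered trajectory equal
the nominal retention exactly in the noiseless case), square-wave open/shut
struggle, iris drift or conjugate sinusoidal wander, arm-angle decay with
an optional single-frame drop, a logistic hip rise, counting transcripts
with deletions, junk-word misrecognitions and a breath pause, and
sinusoidal lip motion. Noise is i.i.d. Gaussian jitter per landmark
coordinate, default sd 0.25 px — calibrated so control lid recordings show
at most ~4% filtered aperture variation at a 20 px aperture, matching what
control recordings exhibit; 0.5 px jitter was measured to produce up to
~7% filtered variation, outside the control envelope. All generators are
deterministic given the seed.

What the generator does **not** emulate — and what passing tests therefore
do not certify about real recordings: correlated landmark jitter (real
detectors err coherently, not i.i.d.), head pose changes other than the
modelled backward tilt, blinks and tracking dropouts, lighting-driven
confidence fluctuation, ASR word-boundary noise, off-axis camera geometry,
and any physiological coupling between exercises. Problem sizes used in the
regression and acceptance suites (60–150 s sessions at 25 fps, cohorts of
50–200 sessions, 10,000 normative draws) were chosen to give stable rate
estimates while keeping the suite quick on one CPU.

## Numerical and degenerate-input conventions

OLS fits require ≥ 3 samples and ≥ 2 distinct times; all-equal times raise
a degenerate-input error. Crossed lids clamp the aperture to 0 and flag the
frame. Zero-length arm or torso vectors raise a geometry error. A
below-threshold dip reaching the end of an arm recording counts as
sustained failure (no recovery was observed). Sampling gaps over two frame
periods inside an acceleration window raise an error rather than silently
differentiating across a hole. Reports serialize with sorted keys;
identical inputs and configuration produce byte-identical JSON.

## Limitations

Quantification is only as good as the upstream landmark detector and ASR;
the package propagates their confidences but cannot correct them. Vertical
ocular misalignment is not measured. Cheek-puff and tongue-protrusion
exercises resist landmark-based quantification and are excluded. The
shipped norms derive from a small control panel with implied SDs; they are
placeholders until site-computed norms exist. Breath-pause detection
conflates recognizer dropouts with true silences. The sit-to-stand metric
covers the ascending phase only.
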