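# mgce — digital metrics for the Myasthenia Gravis Core Examination

`mgce` turns the standardized telemedicine neuromuscular exam for myasthenia
gravis (the MG-CE: sustained upgaze, eccentric gaze, arm extension,
sit-to-stand, count-to-50, single-breath count) into continuous, objective
measurements. It consumes what video post-processing pipelines already
produce — time-stamped anatomical landmark series in pixels and word-level
ASR transcripts — and computes per-exercise fatigue metrics, applies
control-derived normative thresholds, and flags abnormality. A synthetic
exam generator with known ground truth makes the whole pipeline testable
without any patient recording.

It is written for clinical-research engineers and neuromuscular study teams
who need exam quantification that is reproducible, auditable, and decoupled
from any particular landmark detector or ASR vendor.

## The metrics

With landmark positions in image coordinates (y grows downward) and time in
seconds:

- **Ptosis (lid fatigue).** The palpebral aperture a(t) = y_lower_lid −
  y_upper_lid is median+mean filtered over 0.5 s; the retention score is
  `retained_pct = 100 · Q_q(a) / Q_{1−q}(a)` (robust extremes, q = 0.05),
  invariant to camera distance. Fatigue is `stable` when the filtered change
  is within the 4% control noise bound, `linear_fatigue` when an ordinary
  least squares fit a(t) ≈ β₀ + β₁t has β₁ < 0 with R² ≥ 0.6, else
  `unstable` (open/shut struggle). Backward head tilt (a compensation that
  corrupts the measurement) is detected from the chin-to-crown extent.
- **Ocular misalignment.** Each iris is reduced to a barycentric coordinate
  b = (x_iris − x_inner) / (x_outer − x_inner) within its fissure; after
  mirroring the left eye, conjugate gaze cancels and m(t) = b_L − b_R
  indexes misalignment (0 = aligned). The summary is the OLS slope of m
  times the exercise duration; |drift| < 0.05 is below the resolvability
  floor of consumer video and flagged indeterminate.
- **Arm endurance.** The angle θ(t) between the shoulder→wrist vector and
  the torso axis (mid-shoulder→mid-hip) is held near π/2 for up to 120 s.
  Hold time runs until the median-filtered angle stays below 60° for ≥ 1 s;
  drift is the OLS slope over the held window × hold time (radians over the
  test, negative = downward). Thresholds: −0.12 rad (age ≤ 70) and
  −0.24 rad (> 70), i.e. control mean − 1 SD.
- **Sit-to-stand.** The ascending phase is the interval around peak upward
  mid-hip velocity where velocity exceeds 10% of the peak; inability to
  stand is a total hip rise under half the trunk length.
- **Counting speech.** Number tokens (digits, number words, adjacent-word
  compounds, counting homophones) are parsed from the transcript; the
  exercise is the longest strictly increasing run starting at ≤ 2 with a
  bounded budget for missing/misrecognized values. Outputs: elapsed time,
  onset-interval mean and CV, count reached before the first breath pause
  (inter-token gap > 1 s).
- **Lip acceleration.** The upper-lip position normalized by mouth width,
  differentiated twice by central differences; mean |u''| over the counting
  window drops with orofacial weakness.
- **Normative flagging.** Every summary metric is compared to control
  mean ± 1 sample SD (direction per metric), stratified at 70 years
  (strictly older enters the older stratum); a value exactly on the
  threshold is normal.

## Worked example

```python
from mgce import PtosisSpec, SyntheticSpec, analyze_ptosis, gen_ptosis_session, load_config

cfg = load_config()
spec = SyntheticSpec(seed=42, ptosis=PtosisSpec(true_retained_pct=82.0, pattern="linear"))
series, truth = gen_ptosis_session(spec)
result = analyze_ptosis(series, cfg)
```

Running `python examples/ptosis_fatigue.py` (which does the above) prints:

```
left eye: retained 81.6% of maximum aperture, drift -0.074 px/s, pattern: linear_fatigue
right eye: retained 81.8% of maximum aperture, drift -0.072 px/s, pattern: linear_fatigue
head tilt compensation: False
```

The synthetic eye was generated to retain 82% of its maximal aperture under
a linear droop with realistic landmark jitter; the analyzer recovers the
score within a fraction of a percentage point, identifies the linear fatigue
pattern, and finds no head-tilt compensation. A control eye scores ≥ ~96%
(the 4% filtered noise bound), so both eyes here would be flagged ptotic
against the shipped norms.

The other scripts in `examples/` cover ocular misalignment and diplopia
timestamps, arm endurance and drift flags, sit-to-stand timing,
count-to-50 / single-breath segmentation, lip acceleration, and a full
six-exercise session report.

## Command line

```bash
mgce simulate --exercise all --seed 7 --out session/ --truth truth.json
mgce analyze --landmarks ptosis=session/ptosis.json \
             --transcript count50=session/count50_transcript.json \
             --landmarks count50=session/count50.json --out report.json
mgce norms --controls controls.csv --metric arm.drift_total --out norms.json
mgce config --defaults
```

Reports are JSON with sorted keys: identical inputs and configuration give
byte-identical output.

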