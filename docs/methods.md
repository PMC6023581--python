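# Methods

This note documents the models and procedures implemented in `hipposture`,
the conventions adopted where the method leaves details open, what the
synthetic cohort generator does and does not emulate, and the numerical
choices that matter.

## Problem setting

Large prospective cohort studies measure physical activity with hip-worn
triaxial accelerometers, but the conventional way of scoring sedentary time
from these devices — a fixed threshold of 100 counts per minute (cpm) on
the vertical axis — cannot distinguish quiet standing from sitting and
badly distorts the *pattern* of sitting (bout lengths, sit-to-stand
transitions), even when total sitting time looks right.  Thigh-worn
inclinometers (activPAL-class devices) measure posture directly and serve
as ground truth, but are rarely deployed at cohort scale.  `hipposture`
implements a posture classification pipeline for the hip device trained
against thigh-inclinometer labels, alongside the cut-point comparator, so
the two approaches can be compared bout-by-bout.

## Ground-truth labels

Thigh-inclinometer event files contain intervals of `sedentary`,
`standing`, or `stepping`.  Labels are assigned to every second (a second
belongs to the event covering its midpoint).  The two transition classes
are not present in event files and are derived: at every contiguous
boundary between a sedentary event and an upright (standing or stepping)
event, the **first second of the succeeding event** is relabeled
`SIT_TO_STAND` or `STAND_TO_SIT`.  One second matches the brevity of real
postural transitions and conserves total duration.  Standing↔stepping
boundaries produce no transition label.  Gaps between events are an error
by default; an opt-in policy marks gap seconds with a non-wear sentinel
that excludes them from training, testing and bout detection.

A consequence worth stating plainly: because transitions last exactly one
second, **no 5-s window is ever purely a transition class**.  Training is
restricted to pure windows (below), so the forest never sees a transition
example and never predicts one; transition sensitivity is exactly 0 and
specificity exactly 1, giving a balanced accuracy of exactly 0.50 — the
degenerate floor.  The per-fold `in_training` flag in the evaluation output
records which classes a fold could actually learn.

## Feature extraction

The raw, unfiltered signal is split into non-overlapping 5-s windows (150
samples at 30 Hz; a trailing partial window is discarded).  Each window is
summarised by 41 features, in this canonical order:

| group | features |
|---|---|
| vector-magnitude descriptors | `mean, sd, coefvariation, min, max, 25thp, median, 75thp` |
| correlations | `autocorr` (1-s lag), `corrxy, corrxz, corryz` |
| per-sample angles | `avgroll, avgpitch, avgyaw, sdroll, sdpitch, sdyaw` |
| gravity angles | `rollg, pitchg, yawg` |
| spectral | `fmax, pmax, fmaxband, pmaxband, entropy, fft1..fft15` |

with `v = (x² + y² + z²)^½`, `roll = atan2(y, z)`, `pitch = atan2(x, z)`,
`yaw = atan2(y, x)` (radians, arithmetic averages over the window).

Conventions adopted where the method statement is silent:

* **SD** is the sample standard deviation (ddof 1); `coefvariation = sd/mean`
  with 0 substituted when the mean is 0.
* **Correlations** (including the lag-one-second autocorrelation, computed
  as the Pearson correlation of the window's vector magnitude with itself
  shifted by `rate` samples) are 0 whenever either series has zero
  variance: constant windows carry no oscillatory information.
* **Gravity direction** is the per-axis mean after an order-2 Butterworth
  low-pass at 0.5 Hz applied forward and backward (zero-phase, 4th-order
  effective).  Only the cutoff is load-bearing; tests compare against a
  coarse moving-average oracle at loose (0.05 rad) tolerance.  Gravity
  components smaller than 1% of the gravity magnitude are snapped to zero
  before the arctangents: such components contribute under 0.6° to any
  well-conditioned angle but would otherwise flip `atan2` between ±π/2 on
  residual filter leakage when the other argument is zero.
* **Spectrum**: one-sided periodogram of the mean-removed vector magnitude,
  power = |FFT|²/n, zero-frequency bin excluded everywhere.  `fmax/pmax`
  search the full spectrum (ties → lowest frequency); `fmaxband/pmaxband`
  the closed band [0.3, 3] Hz; `fftk` sums the half-open band
  [k−0.5, k+0.5) Hz for k = 1…15 (integer-centred 1-Hz bands give exactly
  15 features up to the 15 Hz Nyquist); entropy is Shannon entropy in nats
  of the spectrum normalised to sum 1, with 0·log 0 ≡ 0.  A window whose
  residual power is numerically zero returns 0 for every spectral feature.

## Classification

Windows are labeled from the per-second truth: *pure* windows (all five
seconds one class) carry that class; impure windows get the majority class,
with ties resolved in favour of a transition class present in the window
(sit-to-stand first), then by the fixed order SIT < STAND < STEP.  Only
pure windows train; all windows are scored at test time.

The classifier is an ensemble of 500 decision trees.  Each tree is grown on
a bootstrap sample (with replacement, fraction 1.0) of the training windows
and a fixed random subset of 6 features — round(15% × 41) — drawn **per
tree**, not per split.  This is `sklearn` `BaggingClassifier` over
`DecisionTreeClassifier` (Gini impurity, minimum leaf 1); the per-tree
feature subsampling is why the stock `RandomForestClassifier` (per-split
subsampling) is not used.  Window probabilities are the average of per-tree
class probabilities; classes absent from training receive 0.

Tree depth is capped at 16 by default (`ForestConfig.max_depth`, settable
to `None`).  With tens of thousands of training windows, trees whose
6-feature subset misses every informative feature otherwise grow to depths
near 60 memorising bootstrap noise — several times the training cost for no
change in the averaged prediction (hold-out accuracy agreed to the third
decimal in our measurements).  Depth 16 admits over 65 000 leaves, far more
structure than 41 features express on this problem.

**Cross-validation** is leave-one-participant-out: every participant is the
test subject in turn; the training fold pools the pure windows of all other
participants, so no within-person information reaches a test fold.  An
explicit audit (`audit_leakage`) verifies fold disjointness.

## Transition filtering

Decoding assigns each window its most probable class (ties by fixed class
order), then two passes repair implausible transitions:

1. adjacent transition pairs: the member with the lower probability for its
   own transition label is reassigned to its most probable non-transition
   class, repeated to convergence (a run of ≥3 transitions can expose a new
   pair after a removal; the pass-level statement covers only pairs).  On a
   probability tie the later window is reassigned.
2. context validity, one left-to-right sweep: `SIT_TO_STAND` requires SIT
   before and STAND or STEP after; `STAND_TO_SIT` requires STAND or STEP
   before and SIT after.  Sequence-boundary transitions have a missing
   neighbour and are invalid.  Invalid transitions are reassigned as above.

Filtering never alters a non-transition label, never increases the number
of transition windows, and the composed filter is idempotent (pass one
guarantees transition neighbours are non-transitions, which pass two never
touches).

## Evaluation

Per class: sensitivity `TP/(TP+FN)`, specificity `TN/(TN+FP)` on the
one-vs-rest collapse of the 5×5 confusion matrix, balanced accuracy their
mean.  Metrics are computed per participant and averaged unweighted;
classes absent from a participant's truth are undefined (NaN) for that
participant and excluded from the average, with the contributing count
reported.  The confusion matrix is pooled (summed) across participants.

## Bout analytics

* **Wear time**: non-wear is any run of ≥90 consecutive zero-count minutes,
  tolerating interruptions of ≤2 consecutive non-zero minutes when each
  interruption has ≥30 min of zeros on both sides (parameters 90/2/30,
  configurable).  Implemented greedily over the run-length encoding and
  verified against an independent block-enumeration reference.
* **Cut point**: a wear minute is sedentary iff its vertical-axis count is
  strictly below 100 cpm; non-wear minutes are neither sedentary nor
  active.
* **Wear matching**: ground-truth seconds falling in accelerometer non-wear
  minutes are excluded, so all methods are compared over a common wear
  time.  Sub-minute alignment assigns each second to the minute containing
  it.
* **Bouts**: maximal runs of sitting epochs (1-s truth stream, 5-s
  machine-learned stream where transition windows delimit and are not part
  of bouts, 1-min cut-point stream).  A sit-to-stand transition is counted
  at each bout followed by a non-sitting *wear* epoch; a bout truncated by
  end of wear or end of data contributes no transition.  Bouts never span a
  non-wear gap; a bout is attributed to the day containing its start.
* **Bins**: half-open, left-closed: [0,2), [2,5), [5,10), [10,20),
  [20,30), [30,60), [60,90), plus an overflow bin [90,∞) so that per-bin
  minutes always sum to total sitting minutes and per-bin counts to the
  bout count.  Day summaries are averaged unweighted over days per
  participant and method; the long-format table (participant, date, method,
  bin, count, minutes, totals, transitions, wear) is what a day-level
  clustered model fit would consume — the model fitting itself is out of
  scope here.

## Synthetic cohort generator

The generator emulates the free-living structure the pipeline assumes, at a
scale that keeps a full experiment on one CPU comfortable: 8 participants ×
480 worn minutes (one day each).  Defaults were chosen once to match
published free-living magnitudes proportionally (roughly 59–65% of the worn
day sitting, a mean sitting bout near 10 min, about one sit-to-stand
transition per 15 worn minutes):

| parameter | default | meaning |
|---|---|---|
| `sit_bout_minutes` | log-normal, median 6 min, σ=1.0 (mean ≈ 9.9) | long-tailed sitting bouts |
| `stand_bout_minutes` | log-normal, median 2.5 min, σ=0.8 | standing segments |
| `step_bout_minutes` | log-normal, median 1 min, σ=0.8 | stepping segments |
| `upright_split` | 0.4 | first upright segment is stepping |
| `upright_continue_prob` | 0.5 | upright period gains another (alternating) segment |
| `orientation_sit` | (sin 0.7, 0, cos 0.7) | hip device pitched ~40° when seated |
| `orientation_stand/step` | (0, 0, 1) | vertical axis along gravity upright |
| `noise_sd_g` | 0.05 | Gaussian sensor noise per axis |
| `gait_freq_hz`, `gait_amp_g` | 1.8 Hz, 0.3 g | vertical gait sinusoid while stepping |
| `count_scale`, `count_noise_max` | 1.0, 80 | count surrogate (below) |

Days alternate sitting bouts and upright periods (days start seated);
transition seconds are rendered as 1-s linear orientation ramps.  The
per-minute count surrogate is
`round(1000 × stepping-fraction × count_scale) + U{0,…,79}` — deliberately
**not** the proprietary count algorithm; it reproduces only the
threshold-relevant ordering (sitting ≈ standing < 100 ≤ stepping), which is
exactly the property that makes the cut point misclassify standing as
sedentary.  Everything derives deterministically from the root seed through
per-participant sub-streams.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: realistic postural dynamics inside transitions
(a 1-s linear ramp is a stand-in), vehicle travel, device misorientation or
re-positioning, non-Gaussian sensor artefacts, circadian structure, or the
true count algorithm.  Recovery results on this cohort demonstrate that the
pipeline's machinery is correct and well-calibrated under its own
assumptions, not that the classifier reaches any particular accuracy on
free-living humans — on real cohorts the reported accuracies are far lower,
precisely because real transitions and "messy" behaviour are harder than
this model.  The class imbalance the pipeline must cope with (transition
windows ≪ 1% of windows) *is* reproduced.

## Problem sizes and determinism

The default experiment (8 participants × 480 min, 500 trees × 8 folds) was
chosen as the smallest cohort that exercises every stage with realistic
class imbalance; it runs leave-one-participant-out end to end in roughly
ten minutes on one CPU.  All randomness — schedules, signals, counts,
bootstraps, feature subsets — flows from explicit integer seeds;  repeated
runs are bit-identical.
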