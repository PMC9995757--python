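# Methods

This note documents the models, algorithms and design choices behind
`nearfall`: a pipeline that turns raw logs from a five-sensor body-worn
IMU array (chest, both thighs, both shanks; 100 Hz tri-axial
accelerometer + gyroscope) into labeled activity streams, behavioral
fall-risk biomarkers, and a fall-frequency regression model.

## Sensor and session model

Each sensor log is a time-stamped stream of specific force (m/s²) and
angular rate (rad/s).  A session bundles the five placements; clocks are
reconciled by adding a per-sensor declared offset (offsets are inputs —
this package does not estimate them), restricting to the common overlap
interval, and linearly interpolating every channel onto a uniform grid
at the nominal rate (100 Hz).  Session time is relative: t = 0 at the
start of the overlap, and annotations share this base.  The magnetometer
is parsed but unused: heading estimation is out of scope.

## Tilt observer

Segment inclination is estimated per placement with a switched-gain
complementary observer.  Writing θ for the sagittal tilt, ω for the
pitch-gyro reading and b for the (unknown, constant) gyro bias, the
discrete observer on a grid of step dt is

    θ̂[k+1] = θ̂[k] + dt·(ω[k] − b̂[k]) + K_θ[k]·(θ_acc[k] − θ̂[k])
    b̂[k+1] = b̂[k] − K_b[k]·(θ_acc[k] − θ̂[k]),   θ_acc = atan2(a_x, a_z)

The accelerometer inclination θ_acc is trustworthy only when the
measured specific force is close to gravity; the gain therefore switches
on | ‖a‖ − g |:

* quasi-static regime (deviation ≤ 1.5 m/s²): K_θ = 0.02 per 10 ms step
  (accelerometer-trusting),
* dynamic regime (deviation > 1.5 m/s²): K_θ = 0.002 (gyro-trusting).

K_b = K_θ/10 in both regimes; gains rescale linearly for other grid
steps.  Initialization is θ̂₀ = θ_acc at the first sample, b̂₀ = 0.  The
two-state error dynamics are linear and stable; with the default gains
the slow (bias) mode has a time constant of roughly 10 s at 100 Hz, so
a constant bias is absorbed well within a one-minute recording.  The
gains are fixed constants chosen to satisfy the benchmark below — no
LMI-based gain synthesis is performed, and only pitch is estimated
(in-plane assumption).  Benchmark (60 s of 0.3·sin(2πt) tilt, default
sensor noise, bias 0.05 rad/s): RMSE ≈ 0.5° after a 5 s burn-in and
terminal bias error ≈ 6·10⁻⁴ rad/s.

## Synthetic sessions

The simulator stands in for home recordings; no real data ships with
the package.  An activity script is drawn from a class mix over eight
activities (stand, walk, turn, sit, bend, lie down, near-fall, fall);
a posture grammar inserts `stand_to_sit` / `sit_to_stand` transfers so
upright↔seated changes always pass through a transfer, and lying is
entered via sitting.  Scripts map deterministically to per-segment
kinematics (all stochastic parameters are drawn at script time):

* **stand**: every segment vertical (pitch 0); **sit**: thighs at π/2,
  shanks and chest vertical; **lie down**: all segments at π/2.
* **walk**: thigh/shank pitch oscillation at the scripted cadence
  (drawn uniformly from 0.8–1.2 Hz), amplitudes 0.30/0.55 rad with
  left/right in anti-phase, plus a 2×cadence vertical bounce in the
  linear-acceleration envelope.
* **turn**: sustained yaw-rate plateau (|peak| 1.4–2.2 rad/s, random
  direction, 0.5 s ramps) over low-amplitude stepping.
* **bend**: chest pitch to ~π/4 and back over the segment.
* **near-fall**: chest-pitch excursion of 0.5 rad completing within
  ≤ 0.7 s (peak rate ≥ 2.2 rad/s, full recovery well inside 2 s) plus a
  7 m/s² chest specific-force transient at the excursion peak.  These
  thresholds are simulator conventions for a recoverable balance
  perturbation, not claims about real near-fall kinematics.
* **fall**: transition into a sustained lying posture with a 9 m/s²
  impact transient.

Posture baselines are blended with a 0.2 s Gaussian low-pass so
trajectories are continuous across segment boundaries.  Sensor synthesis
places gravity in the sensor frame, so a static noise-free posture reads
exactly 9.81 m/s², the pitch gyro is the discrete derivative of the tilt
trajectory, and the linear-acceleration envelope is gravity-aligned
(specific-force magnitude = g + envelope).  Noise defaults: white accel
noise 0.3 m/s², white gyro noise 0.02 rad/s, constant per-axis gyro bias
uniform in ±0.05 rad/s.  One master seed drives script, bias and noise;
output is bitwise-reproducible.

The default class mix enriches rare events (near-fall 12%, fall 4% of
drawn segments) relative to unconstrained daily life, mirroring a
validation protocol in which subjects deliberately perform detectable
activities.  What the simulator does **not** model: mounting
misalignment, soft-tissue artifact, magnetometer output, 3-D
(out-of-plane) motion, biomechanically exact gait, and the long
heavy-tailed sedentary stretches of real home days.  Passing tests on
this generator therefore demonstrate pipeline correctness and
end-to-end learnability under controlled conditions — not field
performance on patients.

## Windowing and recognition

Sessions are cut into 2.0 s windows with 0.5 s stride (a window covers a
gait cycle or a transfer; values are configurable).  Each window carries
seven channels: the five estimated segment tilts, chest specific-force
magnitude, and chest yaw rate.  The two chest channels are deliberate
additions to the tilt set: near-fall transients live in the force
magnitude, and turning is invisible in sagittal tilt alone.  Labeled
windows take the class covering the largest fraction of the window
(ties break in canonical class order, `stand` first).

Four classifier kinds share one interface:

* **lstm** — the sequence model: conv1d(16, kernel 5) → max-pool(4) →
  conv1d(32, kernel 5) → max-pool(4) → LSTM(64) → dense softmax over the
  present classes.  Implemented in numpy with explicit reverse-mode
  gradients; Adam (lr 3·10⁻³), gradient-norm clipping at 5, weighted
  cross-entropy, ≤ 80 epochs with early stopping (patience 15) on a 20%
  validation split; fully seed-deterministic.
* **log / svm / dt** — standard scikit-learn models fitted on per-channel
  summary features (mean, sd, min, max, dominant frequency), since none
  is a sequence model.  SVM probabilities come from sigmoid calibration
  of the decision values.

Class imbalance is handled with square-root-damped inverse-frequency
class weights: full inverse-frequency weighting made rare classes fire
on windows that merely straddle an event boundary, which costs more
stand/walk sensitivity than it buys near-fall sensitivity.

Prediction over stride-contiguous windows applies a centered moving
average of width 3 to the probability sequence before the argmax
(`temporal_smooth`, off by default on the low-level `predict`, on in the
`label_session` pipeline).  Rationale: activity streams are temporally
coherent and predicted streams form contiguous blocks; a genuine
near-fall spans several overlapping windows and survives the filter,
while isolated boundary-window flips — windows whose majority label is
`stand` but which contain 40% of a transfer or near-fall — are damped.
Measured on held-out sessions this raises stand sensitivity by 2–4
points and also improves near-fall sensitivity.

Per-window labels are merged into events by a width-3 majority filter
and run-length merging; `near_fall` and `fall` windows are exempt from
both the filter and any minimum-event-length absorption, so a
single-window near-fall is never smoothed away.

## Evaluation

The evaluation unit is the window.  One-vs-rest confusion counts per
class give TPR (sensitivity), TNR (specificity), PPV, NPV and ACC; any
zero denominator yields an NA marker, never 0 and never an exception.
ROC curves sweep thresholds over the per-class scores; the trapezoidal
AUC equals the Mann–Whitney pairwise-concordance statistic with
half-credit for ties (property-tested against a brute-force oracle).
An event-level mode pairs each annotated event with the dominant
predicted label, requiring ≥ 50% temporal overlap for a match.

On synthetic 30-min train / 10-min test sessions the sequence model
reaches ≥ 0.95 held-out sensitivity for stand, walk and turn, with
near-fall around 0.75–0.85 — the hardest class, as its windows resemble
transfers and bends.  The sequence model's near-fall AUC dominates the
decision tree's across seeds.  The linear baselines are *not* ranked
below the tree here: on clean synthetic kinematics the flattened
summary features are far more informative than on real recordings, so
tree-over-linear orderings observed on field data do not transfer to
the simulator.

## Behavioral biomarkers

From a labeled stream and the chest trace, per subject:

* `Nfall_Count_h`, `Nfall_Freq_h` — near-fall count and per-week
  frequency (per week, sharing units with the outcome).
* `Tot_Num_Abs` — number of ambulatory bouts: maximal unions of
  walk/turn events separated by gaps ≤ 2 s (configurable).
* `Sit_Freq_h`, `walk_freq_h`, `lie_down_freq_h` — class time fractions
  of total monitored time.
* `peak_acc_h` — per day, the maximum of | ‖a‖ − g | on the chest;
  aggregated across days by the mean (the aggregator is a choice; mean
  is the least outlier-dominated of mean/median/max here).
* `alpha_8` — continuous maximum-likelihood (Hill-type) power-law
  exponent of bout durations above d_min = 8 s:
  α̂ = 1 + n / Σ ln(dᵢ/d_min), undefined (NA) below 10 qualifying bouts.

Missing inputs propagate NA markers, never silent zeros.

## Fall-frequency model

The outcome is prospective fall frequency (falls/week from diaries).
Features are screened by Pearson correlation with the outcome
(pairwise-complete over missing data; constant features are NA and never
ranked).  The regression is a fixed five-term OLS —

    fall_freq ~ 1 + Nfall_Freq_h + Tot_Num_Abs + Sit_Freq_h + updrs + alpha_8

— fitted complete-case, reporting per-term estimates, standard errors,
t = estimate/SE with two-sided Student-t p-values on n − 6 df, and the
ANOVA decomposition (Total/Model/Residual SumSq and MeanSq,
F = MeanSq_model/MeanSq_residual with its F(5, n−6) p-value).  The
implied design has df_model = 5 and df_residual = 10 (n = 16) in the
reference setting.  No multiple-testing correction is applied.  Rank
deficiency raises a collinearity error naming the offending columns; a
numerically perfect fit reports zero SEs and NA t-statistics.  Type-I
calibration at n = 16, p = 5 is Monte-Carlo verified (rejection rate
5% ± 2% at the nominal 5% level).

## Numerical and testing choices

* Problem sizes: the end-to-end check trains on one 30-minute synthetic
  session (~3,600 windows) and evaluates on 10 minutes; exponent
  recovery uses n = 10⁵ bout durations; the type-I calibration uses
  2,000 replicates.  These sizes give stable statistics while keeping
  the whole suite fast.
* Windows use inclusive endpoints (2 s at 100 Hz → 201 samples); events
  produced from window labels span one stride per window.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; training, simulation and prediction are
  reproducible end to end.
* Undefined statistics are NaN in memory and rendered "NA" in reports.

## Known limitations

* Single-axis (sagittal) tilt only; turns contribute yaw rate but no
  3-D orientation is estimated.
* The observer's switching criterion (specific-force magnitude) is one
  of several reasonable operationalizations of "trust the gyro during
  high dynamics".
* Near-fall detection degrades on windows that straddle event
  boundaries; per-window sensitivity for near-falls (~0.8) is
  intrinsically below the common classes.
* The simulator's separability is optimistic for the flattened-feature
  baselines; cross-classifier comparisons made on it say little about
  relative performance on patient data.
* The fall model's cohort-scale statistics (correlations of specific
  biomarkers with observed falls) require real cohorts; the package
  verifies the machinery, not those effect sizes.
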