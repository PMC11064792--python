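# Methods

This note documents the models, numerical choices and open design decisions
behind `wrikit`, and what the simulation-based tests do and do not establish
about real recordings.

## Task and data model

The WRI task yields, per child, two six-channel inertial time series (one per
wrist) at a nominal 50 Hz: acceleration in g, angular velocity in deg/s. The
protocol clock defines the block structure — recording starts at block-1
onset; block *k* occupies the half-open window
[k·(20+10), k·(20+10)+20) seconds — so segmentation needs no activity
detection. The y-axis is the pronation/supination axis; only the `gy`
channel enters the metrics. Recordings in other units or axis conventions
must be converted at read time. Duplicate timestamps are dropped (first
kept) because interpolation requires strict monotonicity; a series sampled
on [0, T) is accepted as covering a T-second protocol (one-sample slack).

## Conditioning chain

1. **PCHIP interpolation** to the uniform grid. Shape-preserving cubic
   Hermite avoids overshoot on monotone segments, so dropped samples do not
   manufacture spurious angle extrema.
2. **Zero-phase Butterworth**, 2nd order, 10 Hz cut-off, applied
   forward–backward (`filtfilt`, odd-reflection padding of one settling
   length). Zero phase was chosen because the metrics depend on peak timing;
   the squared magnitude response still passes the ~2 Hz task band within
   0.2%.
3. **Scalar Kalman filter**, local-level (random-walk) state per channel,
   gain K = P/(P+r). Defaults: process variance q = 10⁻²·var(channel);
   measurement variance r estimated robustly from **second differences**
   (Var(Δ²x) = 6σ² for white noise, MAD-based). A first-difference estimator
   was rejected: at 50 Hz a 2 Hz oscillation's slope dominates first
   differences, inflating r and attenuating the signal itself by >10%; the
   second-difference estimator keeps the steady-state gain near 1 for the
   band-limited rotation while still smoothing residual wide-band noise.
   The filter is causal; its small group delay is common to both wrists and
   does not affect any metric.

## Metric definitions and numerics

* **Angle trace**: trapezoid integration of `gy`, then linear detrend — this
  removes the ramp a constant gyro bias leaves in the integral, making RoA
  bias- and sign-invariant.
* **Extrema**: local maxima/minima of the detrended angle with prominence
  ≥ 10° and spacing ≥ 0.15 s (a 2 Hz rotation's extrema are 0.25 s apart).
  The "peak points" of the RoA definition are read as extrema of the
  *angle* (equivalently zero crossings of ω): integrating ω between adjacent
  peaks of ω itself would give ≈ 0 for any symmetric oscillation, so the
  angle-extrema reading is the one under which RoA is an "averaged rotation
  angle". N is the extrema count (an N−1-term sum over adjacent pairs
  forces that reading).
* **RoF** has no canonical formula; it is defined as
  (N−1) / (2·(t_N − t_1)) — half-cycles per second halved — which recovers
  the generating frequency within 0.1% on clean signals.
* **TRT** activity rule: moving RMS of `gy` over 0.5 s; threshold
  max(15 deg/s, 0.2 × 95th-percentile RMS); inactive gaps shorter than
  0.5 s are bridged. All three knobs are configurable; the defaults place
  the threshold well above the conditioned noise floor (a 20 deg/s-noise
  block that contains no rotation stays below it) yet far below the
  ≈ 565 deg/s peak rate of a 45°/2 Hz rotation.
* **Scoring wrist**: TRT and RoA use the dominant (right) wrist — the study
  population was entirely right-handed — with a `wrist_policy="max"`
  option. Symmetry always uses both wrists; its 0.7/0.3 weights are fixed
  constants of the definition. Each normalised difference is defined as 0
  when both arguments are 0, so two motionless wrists count as symmetric;
  values are squared and clipped to [0, 1].
* A participant with fewer than two angle extrema in every block is flagged
  `low_motion` and scored (0, 0, 0).

## Simulator

The generator models what the task produces rather than arm biomechanics:
per wrist, θ(t) = Θ·w(τ)·sin(2πf τ) on block-local time, with w a raised-
cosine envelope that is 1 until `sustain_s` and decays over 1 s. The
gyroscope reports the analytic dθ/dt plus bias and white noise; the
accelerometer reports gravity re-projected through θ (rotation about the
wrist axis) plus white noise — no linear-acceleration term, since no
accelerometer-derived quantity enters the metrics. Rest periods are noise
only. Sessions are byte-deterministic given a seed.

Cohort presets encode the clinical contrast directions (autistic children:
shorter sustain, smaller amplitude, lower left/right ratios) with per-child
log-normal variation:

| parameter | TD mean (CV) | ASD mean (CV) |
|---|---|---|
| Θ, deg | 60 (0.25) | 40 (0.25) |
| sustain, s | 20 (0.50) | 11.5 (0.80) |
| L/R amplitude & frequency ratio | 0.95 (0.10) | 0.75 (0.18) |
| f, Hz | 2.0 (0.05) | 2.0 (0.05) |

plus a 0.9/1.0/1.1 amplitude gradient across the three age bands (amplitude
grows with age; sustain and symmetry do not). The sustain means/CVs were
calibrated once so the cohort-level standardised group difference on TRT is
≈ −1.6 — the magnitude reported for the clinical cohort — under default
noise (8 deg/s gyro, 0.05 g accel, 0.5 deg/s bias: plausible consumer-MEMS
figures after calibration); the block cap at 20 s compresses TD variance,
which is why the CVs are wide. Default cell counts mirror the study's
demographic table (15/19, 15/20, 19/20; n = 108), whose group×age balance
chi-square is 0.29 (df 2, p 0.87).

**What passing simulated tests shows — and does not.** The simulator
validates signal-path correctness (parameter recovery through conditioning
and metric extraction), the statistics' calibration, and that the advertised
effect directions propagate end to end. It does not validate the metrics
against real wrist kinematics: real recordings contain linear-acceleration
transients, cross-axis motion, pauses and partial imitation, none of which
the generator emulates, and real effect sizes on amplitude/symmetry will
differ from the presets'. Classifier accuracies on simulated cohorts are
properties of the presets, not estimates of clinical performance.

## Calibration

The accelerometer fit is the minimal identifiable form: per-axis bias b and
diagonal scale s minimising Σ(‖s∘(a−b)‖ − 1 g)² over ≥ 6 static poses
(Levenberg–Marquardt from b=0, s=1; a rank-deficient Jacobian at the
solution raises an identifiability error). Cross-axis terms and temperature
are out of scope. The gyroscope is profiled with the overlapping Allan
deviation on log-spaced τ from 2/rate to one ninth of the record, the
standard diagnostic whose log-log slopes identify white rate noise (−½) and
rate random walk (+½). Calibration is optional — simulated data is born
calibrated — and applied per device when a calibration file is supplied.

## Statistics

ART is implemented from its published construction: estimate each effect
from the (unweighted) cell means of the 2×3 layout, align the response for
one effect by adding that effect's estimate to the cell residuals, rank with
average ties, and run a fixed-effects factorial ANOVA on the ranks (Type III
sums of squares, sum-to-zero coding, computed by full-vs-reduced OLS
projections; cross-checked against `statsmodels.anova_lm` in the tests).
Partial η² = SS_effect/(SS_effect+SS_error) is reported — which η² variant
the field reports varies, so it is labelled explicitly. One caveat
discovered in testing: the factorial ART F is *not* exactly invariant to
nonlinear monotone response transforms (alignment uses cell means); the
invariance holds only in the one-way collapse, and the implementation's
calibration is instead established by a 1000-replicate null Monte Carlo
(each effect rejects at ≈ 5%).

ART-C contrasts re-rank the factor-aligned values within the two levels
being compared and t-test those ranks; Bonferroni correction is applied over
the pairwise family within one factor and one metric (no cross-metric
correction, matching the analysis design). Cohen's d uses the pooled-SD
form on raw responses with the ASD − TD sign convention. Spearman
correlations between metrics and clinical scores are deliberately
unadjusted for multiplicity (exploratory analysis); pairs with < 4 complete
observations are reported missing. The chi-square test is Pearson's, no
continuity correction.

## Clinical scales

Gesell DA is the pass-weighted mean of milestone ages, DA = ΣWᵢNᵢ/ΣNᵢ, with
week-valued milestones converted at 4.345 weeks/month (the standard 24-
milestone list mixes weeks and months). No basal/ceiling or partial-credit
rules are applied — the straight weighted mean is the documented form.
DQ = 100·DA/CA; bands: < 76 delay, 76–85 borderline, ≥ 86 normal. CARS
totals 15 items (half-point scores admitted, as in standard practice);
bands: < 30 / 30–36 inclusive / > 36. PEP-3 performance subscales are
containers only — they enter correlation analyses, no formula applies.

## Classification

Pipelines standardise features inside each CV fold (no leakage), select
hyperparameters by stratified 10-fold CV grid search maximising accuracy,
refit on the full training 90%, and report sensitivity/specificity/accuracy
and rank-formulation AUC (ties = ½) on the held-out 10% with ASD positive.
Default grids are small and standard for a 3-feature problem: KNN
k ∈ {1,3,5,7,9}; SVM-RBF C ∈ {0.1,1,10,100}, γ ∈ 1/n_features·{0.1,1,10};
RF trees ∈ {100,300}, depth ∈ {∞,3,5}; Gaussian NB smoothing ∈ {1e-9,1e-6};
LDA none. `tune_and_fit` defaults to 10 CV repeats; the five-algorithm
`run_benchmark` defaults to 3 repeats — the problem size chosen so the full
sweep (the RF grid alone is 600 fits at 10 repeats) runs in about a minute
on one core — and both are configurable. Because an ~11-child test set is a
high-variance measurement, the benchmark also reports repeated-split means
(hyperparameters reused from the primary split), clearly labelled.

## Known limitations

* No orientation estimation (sensor fusion); metrics are single-axis by
  design and assume the watch is worn with the y-axis along the forearm.
* The TRT activity rule and peak-detection thresholds are heuristics tuned
  for ~2 Hz rotation; very slow (< 0.5 Hz) or very small (< 10°) motion
  reads as inactivity.
* The Kalman stage is a light-touch scalar smoother, not a dynamic model of
  wrist motion; with the automatic noise estimates its effect on clean
  signals is < 1%.
* Simulated classifier performance and effect sizes characterise the
  generator presets, not any clinical population.
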