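# Methods

## Problem and pipeline

`glucowear` estimates interstitial glucose (mg/dL, 5-minute cadence) from
passively sensed wrist-wearable signals alone: blood volume pulse (BVP,
64 Hz), electrodermal activity (EDA, 4 Hz), skin temperature (sTemp, 4 Hz),
tri-axial accelerometry (ACC, 32 Hz) and the derived heart rate (HR, 1 Hz).
The unit of analysis is the *epoch*: the 5-minute multi-channel window
immediately preceding one CGM reading. The chain is

1. **preprocessing** — signal preparation, filtering, plausibility masking,
   epoch segmentation, imputation;
2. **feature engineering** — a fixed battery of 236 features per epoch;
3. **feature cleaning and selection** — rule-based column/row cleaning, then
   random-forest importance ranking with the top 30 retained;
4. **regression** — imputer → scaler → regressor pipelines for four families
   (linear, ridge, random forest, gradient-boosted trees), tuned by grid
   search with 5-fold CV and refit on the training partition;
5. **evaluation** — R², RMSE, NRMSE, MARD; Bland–Altman agreement; Clarke
   Error Grid (CEG) clinical accuracy; everything repeated across random
   seeds and averaged.

## Preprocessing choices

* ACC magnitude is `sqrt(x² + y² + z²)`, computed after loading; missing in
  any axis makes the magnitude missing.
* Filters are Butterworth, applied forward–backward (zero-phase) per
  contiguous non-missing segment: BVP band-pass 0.5–5 Hz (order 4), ACC
  magnitude low-pass 10 Hz, EDA low-pass 0.5 Hz (both order 4, matching the
  one stated order). Zero-phase filtering preserves the temporal alignment
  between signal windows and CGM timestamps. Segments shorter than the
  filter warm-up are marked missing. HR and sTemp are never filtered in the
  frequency domain; they receive plausibility masking only.
* Plausibility bounds are closed intervals: HR 25–240 bpm, sTemp 30–40 °C,
  BVP −500–500 a.u., EDA 0.01–100 μS, ACC magnitude 0–68 m/s² (applied to
  the magnitude, whose unit the bound matches). Out-of-range samples become
  missing.
* The epoch window is `(t − 300 s, t]`, left-open right-closed. Each channel
  is resampled onto a nominal grid of `fs × 300` slots; a sample at `rel`
  seconds into the window lands in slot `ceil(rel·fs) − 1`, so a sample at
  exactly the right edge fills the last slot and one at exactly the left
  edge belongs to the previous epoch. Multiple samples per slot are
  averaged; empty slots are missing. Expected slot counts: HR 300, EDA 1200,
  sTemp 1200, ACC 9600, BVP 19200.
* Epochs with **more than** 50% missing in at least one channel are
  discarded (exactly 50% is retained) and counted with a reason.
* Remaining missing slots are imputed epoch-wise: mean if the observed
  distribution is approximately normal (|skewness| < 0.5, adjusted
  Fisher–Pearson estimator, treated as 0 for degenerate inputs), otherwise
  median. Observed samples are never altered.
* A `max_clock_skew` option (default 0 s) widens the sample-matching window
  for data whose wearable and CGM clocks are not perfectly aligned; the
  study conditions assume aligned clocks.

## The 236-feature battery

Fixed, versioned manifest (changing it is a breaking change):

* **Data-driven** (87 per signal, for HR and sTemp): 31 time-domain
  statistics (moments, percentiles, dispersion, difference statistics,
  zero-crossing rate, linear trend, energy, Hjorth parameters, line length);
  14 frequency-domain features from a Welch PSD (Hann window, 50% overlap,
  `nperseg = min(256, n)`): total power, 4 absolute and 4 relative band
  powers on bands partitioning [0, fs/2] (HR: 0–0.05/0.05–0.15/0.15–0.3/
  0.3–0.5 Hz; sTemp: 0–0.05/0.05–0.2/0.2–0.6/0.6–2 Hz), normalised spectral
  entropy, dominant frequency, centroid, bandwidth, 95% spectral edge;
  42 non-linear features in four families — entropy (16), fractal (8),
  complexity (8), recurrence quantification (10).
* **HRV** (13): systolic peaks are detected on the band-passed BVP epoch by
  local-maximum search with a 0.25 s minimum distance (240 bpm bound) and an
  adaptive height threshold (0.5× the rolling 5-s-block 75th percentile);
  the inter-beat-interval series in ms yields meanNN, medianNN, SDNN, RMSSD,
  SDSD, pNN20, pNN50, CVNN, meanHR, stdHR, minNN, maxNN, IQRNN (SD-type
  statistics use the n−1 denominator, the HRV convention). Fewer than 5
  detectable beats ⇒ all 13 missing.
* **EDA** (42): the epoch is decomposed into a tonic component (zero-phase
  low-pass at 0.05 Hz) and the phasic residual, so tonic + phasic equals the
  input exactly. 17 distribution statistics per component plus 8 phasic
  event features from SCR detection (peaks ≥ 0.01 μS above the preceding
  trough; rise time trough→peak; half-recovery capped at 10 s). The
  amplitude/timing event features are missing when no SCR is detected.
* **Behavioral** (3): min/max/mean ACC magnitude over the trailing 2-h
  window, computed from per-5-min-block summaries (exact for min/max and the
  count-weighted mean); all three are missing when less than 50% of the
  window's expected samples are available, mirroring the epoch rule.
* **Circadian** (3): minutes from midnight m ∈ [0, 1440) and sin/cos of
  2πm/1440. Timestamps are interpreted in the participant's local time
  (offset configurable, default UTC).
* **Demographic** (1): biological sex, male → 1, female → 0.

### Non-linear parameter choices

Template length m = 2 with tolerance r = 0.2·SD for the
approximate/sample/fuzzy/multiscale entropies (the field's standard
defaults); embedding dimension 3, delay 1 for recurrence quantification,
correlation dimension and the Rosenstein largest-Lyapunov estimate;
recurrence threshold 10% of the maximum phase-space distance, minimum line
length 2; permutation entropies at orders 3/4/5 (normalised); histogram
entropies on 16 bins; dispersion entropy with 6 classes, length 3;
Higuchi k_max = 10. Sample entropy of a zero-variance vector is defined
as 0 (every template matches). sTemp epochs are block-averaged 4:1 (to 300
points) before the non-linear estimators so that both signals' non-linear
features are computed on series of comparable length; time- and
frequency-domain features always use the native epoch. The time-domain list
and the non-linear complexity family both include Hjorth mobility and
complexity; the duplicate-column cleaning rule therefore deterministically
drops the non-linear copies — the raw battery is nevertheless always 236
columns wide.

## Cleaning, selection, modeling

Column rules in order: > 20% missing (strictly more), overflow (any
non-finite value; a drop-cell policy is available but drop-column is the
default), constant, duplicate (keep the earliest column in manifest order),
variance < 1e-5. Row rules afterwards: any infinity, or > 20% of the
surviving feature cells missing.

The 80/20 split is a pooled epoch-level uniform random split
(|train| = round(0.8·n)); with 26,380 epochs this gives 21,104/5,276.
Feature selection uses impurity (mean-decrease-in-impurity) importances
from a 100-tree random-forest regressor fitted on the median-imputed
training features (`max_features="sqrt"` keeps the ranking affordable on a
laptop-scale CPU); ties break by manifest order; the top 30 are retained.
Selection, imputer medians and scaler parameters are functions of the
training partition only — verified by a corruption audit in the tests.

Model families: linear regression (LR), ridge (RR, penalty grid
{0.01, 0.1, 1, 10, 100}), random forest (RFR, trees {100, 300} × depth
{None, 10, 20} × min-leaf {1, 5}) and XGBoost (XR, trees {100, 300} × depth
{3, 6} × learning rate {0.05, 0.1} × subsample {0.8, 1.0}); all grids are
config-overridable. Grid search minimises mean 5-fold-CV RMSE (folds
shuffled with the repetition seed), then refits on the full training
partition. Repetition i of the protocol uses `base_seed + i` for the split,
the selector forest and the regressors, and repeats the selection per
repetition so it never sees test rows.

## Evaluation

* R² = 1 − SSE/SST; RMSE in mg/dL; NRMSE = RMSE / SD(reference) —
  dimensionless, using the test-set reference SD (population denominator);
  MARD = 100·mean(|predicted − reference| / reference) %.
* Bland–Altman differences are reference − predicted; limits of agreement
  are MD ± 1.96·SD (sample SD).
* CEG zones follow the canonical piecewise boundaries with deterministic
  resolution order A → E → C → D → B (first match wins) and an inclusive
  20% criterion for zone A; an exhaustive 400×400 sweep against an
  independently coded oracle is part of the test suite. Plots colour the
  zones green/yellow/orange/purple/pink (A–E).

## Synthetic cohort generator

The generator emulates the sampling structure of a free-living wearable+CGM
study: the five channels at their native rates over multi-day recordings
(default 9 days, within the 8–10-day span typical of such studies), CGM
every 300 s, and block-wise (5-min) channel dropout emulating non-wear
(default probability 0.05 per channel per block). Glucose follows an
explicit additive model — baseline 110 mg/dL, +8 mg/dL male offset,
circadian sinusoid of amplitude 10 mg/dL, three meals/day with 40 mg/dL
exponentially decaying excursions (decay 60 min, onset times jittered
±30 min SD per day), an activity term (−15 mg/dL per unit 2-h mean ACC
magnitude normalised by the cohort 95th percentile) and AR(1) noise
(ρ = 0.9, innovation SD 5 mg/dL). Defaults were chosen once so the cohort
summary is plausible for a normoglycemic/prediabetic group (mean glucose
≈ 110–115 mg/dL, nearly all readings 70–180 mg/dL); they are configuration,
not truth claims. Every latent component is stored per CGM timestamp and
the emitted glucose is their exact sum, so recovery is testable.

Signals: BVP is a stereotyped beat waveform phase-warped to a latent HR
process (rest 60–80 bpm, elevated during activity bouts), so downstream
peak detection finds genuine beats; the HR channel is the latent HR plus
noise; EDA is a bounded tonic random walk plus sparse SCR bumps with
exponential rise/decay; sTemp is 33.5 °C plus a 0.5 °C daily sinusoid plus
noise; ACC has a gravity baseline with randomly placed oscillatory activity
bouts. One global seed fans out into per-participant, per-channel
substreams, so cohorts are bit-reproducible regardless of generation order.
Sexes alternate across participants so every cohort contains both.

**What the generator does not emulate** — PPG morphology and motion
artifacts, thermoregulatory dynamics, sensor drift, meal composition, or
genuine physiological coupling between EDA/HRV and glucose beyond the
programmed terms. Passing end-to-end tests therefore shows that the
pipeline recovers signal that is present by construction (sex, circadian
phase, meal-time regularities, activity), not that the features would carry
the same information in real cohorts; results on real data remain an
empirical question.

## Problem sizes and numerical notes

The default test-suite study runs the full pipeline on 8 participants ×
9 days (≈ 20,700 candidate epochs; with default dropout ≈ 16,000 retained)
with 5 protocol repetitions comparing a linear baseline against a fixed
XGBoost configuration. The acceptance script uses 6 participants × 6 days
with 3 repetitions and compact grids (one point for the tree ensembles,
the full ridge grid). These sizes are the package's desk-scale defaults;
all of them are parameters.

Degenerate inputs are defined deterministically: zero-variance vectors give
0 for CV-type, Hjorth and entropy features; skewness of a constant sample
is treated as 0 (mean branch); band powers renormalise over the four bands
so relative powers always sum to 1; division-by-zero cases yield missing
values that the cleaning rules then handle. All estimators are pure
functions — the same epoch always produces bit-identical features.

## Known limitations

* Pooled epoch-level splitting lets epochs of the same participant appear in
  both partitions; `run_protocol` reports honest test metrics only w.r.t.
  that design (a participant-level split mode would be the natural extension
  for generalisation claims).
* The exact identities of the 87 data-driven, 13 HRV and 42 EDA features in
  the original study design are not published beyond counts and named
  examples; this package fixes its own concrete manifest with matching
  counts and treats it as versioned configuration.
* NRMSE is sometimes printed with mg/dL units in the CGM literature even
  though an SD-normalised NRMSE is dimensionless; it is treated as
  dimensionless here.
* The EDA decomposition is filter-based (deterministic) rather than
  optimisation-based (e.g. sparse deconvolution); SCR rise/recovery times
  are therefore approximations at 4 Hz resolution.
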