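# Methods

`wristtime` implements the processing chain that turns raw wrist-worn
triaxial accelerometer recordings into 24-hour movement-behaviour
summaries, together with a synthetic signal generator that provides ground
truth for every stage. This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Signal processing

**Resampling.** Raw samples are linearly interpolated onto a uniform grid
at the nominal device rate (default 100 Hz). Grid points inside an input
gap longer than `max_gap_s` (default 1 s) become explicit missing values;
interpolation across recording interruptions would manufacture signal.

**Autocalibration.** Accelerometers drift in per-axis gain and offset.
During stationary wear the measured vector should lie on the unit gravity
sphere, so calibration is estimated from non-overlapping 10-s windows whose
per-axis SD is strictly below 13.0 mg (the same SD family as the non-wear
rule, mirroring established wrist pipelines). The fit iterates a
closed-form step: project the current calibrated stationary means onto the
unit sphere, then refit per-axis offset + gain (plus an optional linear
temperature term, used only when a temperature channel is present and the
data identify it) by least squares toward those targets. Iteration stops
when the mean residual `| ||v|| - 1 |` improves by less than 1e-9 g or
after 1000 rounds; in practice convergence takes tens of iterations, each
of which strictly reduces the residual until the noise floor. Success
requires ≥ 10 stationary windows, sphere coverage (stationary means below
−300 mg and above +300 mg on every axis — without it, offset and gain are
not jointly identifiable) and a final residual under 10 mg. Failures raise
an "uncalibratable" error carrying the partial model; the caller may retry
with donor parameters from the previous/next use of the same device
(`borrow_calibration`, which enforces device identity and refuses donors
that are themselves borrowed).

The model is stored in *apply* convention, `calibrated = gain·measured +
offset`; the equivalent device-space distortion parameters are exposed as
`device_gain = 1/gain` and `device_offset = -offset/gain`. On 100 random
synthetic devices (gain U(0.95, 1.05), offset U(−50, 50) mg, 40 stationary
orientations, 2 mg noise) the median absolute recovery error is well under
5 mg / 0.01 — the benchmark `scripts/acceptance.py` recomputes.

**Clipping.** A reading is "clipped" when any axis magnitude reaches
`dynamic_range − 0.1 g` (saturated MEMS sensors settle slightly inside the
rated ±8 g limit; the 0.1 g margin makes detection robust). Fractions are
computed on the raw and the calibrated signal, since a gain above 1 can
push borderline readings past the margin.

**Noise filter.** A zero-phase 4th-order Butterworth low-pass at 20 Hz
removes sensor noise; gravity removal is delegated entirely to the ENMO
truncation. The filter requires a sampling rate above twice the cutoff and
errors otherwise; the pipeline therefore skips it for grid rates at or
below 40 Hz, where nothing above the pass band survives sampling anyway.
Each contiguous non-missing run is filtered independently.

**ENMO and epochs.** The intensity metric is the Euclidean Norm Minus One,
`max(||v|| − 1, 0) × 1000` mg, truncated at zero so that posture alone
contributes nothing. Signals aggregate into half-open 30-s epochs anchored
at the first sample's timestamp floored to the whole minute — this aligns
the epoch grid with the minute-of-day imputation grid, so a clock minute
always contains exactly two epochs. Epochs with fewer than 50% of expected
samples are missing.

**Features.** Each complete epoch yields 26 features in a fixed documented
order: ENMO mean/SD/max/median/25th/75th percentile; per-axis mean and SD;
the three pairwise axis correlations; ENMO mean absolute deviation,
skewness and kurtosis; roll and pitch mean and SD (`roll = atan2(y, z)`,
`pitch = atan2(−x, √(y²+z²))`); and, from the mean-removed per-sample ENMO
trace, the dominant frequency and its power, total power, and power in the
0.3–3 Hz human-movement band. Degenerate conventions: under zero variance,
correlations, skewness, kurtosis and the dominant frequency are defined as
0. Missing epochs carry NaN markers.

## Non-wear, eligibility, imputation

Non-wear is evaluated on a 1-minute aggregation of epoch statistics: each
minute's per-axis SD pools the within-epoch variances and epoch-mean spread
(i.e. it equals the SD over the minute's raw samples). Maximal runs of
≥ 60 consecutive minutes with all three axis SDs strictly below 13.0 mg
are flagged non-wear; shorter stationary runs stay worn, and missing
minutes break runs. Working at minute granularity matches the ≥ 60-min
episode definition and bounds boundary error at ±1 min.

Eligibility applies four criteria: calibration succeeded (self or donor);
at most 1% clipped readings before and after calibration; at least 72 h of
worn time **and** worn data in every hour of the 24-h cycle pooled across
the whole recording (the pooled reading is consistent with time-of-day
imputation and with the 72 h ≈ 3 days minimum); and an imputed overall
mean acceleration between 1.5 and 100 mg (applied to the imputed mean, as
the bounds describe processed "average acceleration").

Imputation fills interruptions and non-wear by the average of the same
clock minute over the remaining worn days, which removes diurnal wear
bias. Behaviour labels are imputed as fractional (probabilistic) slot
allocations — averaging one-hot vectors — rather than hard labels, which
preserves exact 24-h composition accounting. Slots worn on zero days fall
back to the mean of their hour's observed slots (non-empty whenever hour
coverage holds). Fractions are renormalised to sum to one per slot, so the
four behaviour durations close to 24 h at floating precision.

## Behaviour classification

Training labels are 3-class — sleep, sedentary, non-sedentary — with the
LIPA/MVPA intensity split applied only after temporal smoothing, exactly
in that order. The classifier is:

1. **Balanced random forest** (default 100 trees). Each tree is grown on a
   bootstrap drawing `n_min` samples per class with replacement, `n_min`
   being the minority class size, so free-living label imbalance (sleep
   and sedentary dominate) cannot swamp the rarer classes. Split
   candidates per node are `⌊√26⌋`. Out-of-bag hard votes are retained per
   training sample. With 100 trees the probability that a sample has no
   OOB tree is negligible (≈ 0.63¹⁰⁰); the full-forest prediction is the
   fallback.
2. **Hidden Markov model.** The forest's per-epoch hard predictions are
   the HMM observations. The prior is the smoothed label frequency;
   transitions are counted over consecutive epochs within each participant
   (never across participants); the emission matrix P(predicted | true) is
   counted from the OOB predictions. All counts get add-one (Laplace)
   smoothing so every entry stays positive and no Viterbi path hits −∞ —
   hard predictions with an estimated emission matrix are the simplest
   faithful composition of "forest, then HMM", and they make the decoder
   exactly checkable against exhaustive path enumeration. A soft-emission
   variant was considered and rejected for exactly that testability
   reason.
3. **Viterbi decoding** in log space, ties broken by the fixed state order
   sleep < sedentary < non-sedentary for bit-reproducibility. Note that
   distinct paths can tie *exactly* (identical multisets of factors), so
   the oracle test asserts optimality always, and path identity whenever
   the optimum is unique.
4. **Intensity split.** Smoothed non-sedentary epochs with mean epoch ENMO
   ≥ 100 mg become MVPA, below it LIPA; sleep and sedentary pass through
   untouched.

Missing epochs carry a `missing` label; Viterbi runs per contiguous
observed run.

## Cohort summaries

Participant summaries are read off the imputed profile: behaviour hours are
sums of minute fractions / 60 (closing to 24 h by construction), overall
acceleration is the unweighted mean over the 1440 slots, and hour-of-day /
six-hour-quadrant profiles (00:00–05:59, 06:00–11:59, 12:00–17:59,
18:00–23:59) aggregate slots. Weekday (Mon–Fri) and weekend scalars use
worn epochs only, without imputation.

Cohort accounting applies exclusion reasons in a fixed order (unreadable →
uncalibratable → incomplete questionnaire → insufficient wear-time →
implausible acceleration), removing each participant at the first failing
stage; display rates round half-up to one decimal.

Adjusted group comparisons fit `outcome ~ group + age + sex + region` by
OLS and report **marginal means** by g-computation: the mean model
prediction with group set to g and all covariates at their observed
values. This is the standard "adjusted means" construction; with no
covariates it reduces algebraically to raw group means. Standard errors
propagate the coefficient covariance through the averaged design row. MVPA
is `log(x + 1)`-transformed (the +1 offset accommodates zero-MVPA
participants and is recorded in output metadata), with `exp(m) − 1`
back-transformation and a delta-method SE for display. The linear trend
test refits the model with each group's median entered as a continuous
covariate and reports that slope's t-test; under a simulated null its
type-I error sits at the nominal 5%. The per-decade decline in overall
acceleration is the least-squares slope of group means over group age
midpoints scaled to 10 years, with the relative decline expressed against
the cohort mean.

## The synthetic generator

Real validation recordings for this population are access-controlled, so
the generator is a first-class module that emulates the features the
pipeline must withstand, with known ground truth:

    measured = gain ∘ (orientation + dynamic) + offset + noise,  clipped to ±8 g

- **Schedules.** The `ckb_like` preset follows a diurnal template with
  morning and late-afternoon activity peaks and a midday napping window:
  per day, 8.5 h sleep (including a 1-h nap), 8.25 h sedentary, 5.5 h
  LIPA, 1.75 h MVPA — deliberately in the vicinity of published
  cohort-scale compositions. Waking-segment boundaries get seeded ±5 min
  jitter (sleep totals preserved exactly); day 3 contains a 90-min
  off-wrist episode. `all_sleep` is a degenerate single-segment preset.
- **Dynamic acceleration** is 0.3–3 Hz band-limited Gaussian noise — the
  human-movement frequency band — with per-axis SD `κ·dynamic_sd`,
  κ = 2.0. The scale factor was calibrated once by simulation so that
  mean epoch ENMO ≈ the segment's `dynamic_sd` over the 10–100 mg range
  (a plain SD mapping yields only ≈ 0.5·`dynamic_sd` of truncated-norm
  ENMO); above 100 mg it overshoots (180 mg target → ≈ 210 mg ENMO),
  which only widens the margin to the MVPA threshold. Behaviour intensity
  presets: sleep 3, sedentary 10, LIPA 50, MVPA 180 mg (±10% per-segment
  jitter) — placing each class on the correct side of 100 mg with
  realistic overlap between sleep and sedentary.
- **Movement bursts.** Sleep and sedentary segments receive sparse short
  (2–8 s) bursts (Poisson, 0.6/min and 1.2/min) of elevated dynamic SD —
  posture shifts and fidgeting. These keep sleeping wrists above the 13 mg
  non-wear floor: sleep's quiet baseline SD (≈ 11.7 mg) would otherwise
  read as non-wear over a whole night, while the probability of 60
  consecutive burst-free minutes is ~e⁻³⁶. Non-wear segments alone have
  zero dynamic SD and no bursts.
- **Postures.** Each segment draws a gravity orientation from a
  behaviour-specific pool (sleep mostly horizontal, sedentary mostly
  z-dominant) with small perturbations; the pools span both signs of
  every axis across a week so autocalibration sees the full sphere.
- **Device.** Per-axis gain/offset, white sensor noise (default 10 mg,
  safely below the 13 mg quiet threshold), optional temperature
  coefficient against a sinusoidal daily ambient profile, and hard ±8 g
  clipping.

Ground truth is exact by construction: schedules align to whole minutes,
so 30-s epoch labels conserve scheduled time per behaviour exactly.

**What passing does and does not show.** The generator produces separable,
stationary-in-distribution classes; real free-living data have fuzzier
class boundaries, device artefacts, and annotation noise, so the ≈ 0.99
end-to-end accuracy here demonstrates *pipeline correctness* (plumbing,
units, thresholds, grids, conservation laws), not expected field accuracy.
Conversely the accounting, oracle and recovery benchmarks (cascade rates,
Viterbi vs enumeration, calibration recovery, non-wear boundaries) are
exact properties that transfer as-is.

## Problem sizes and determinism

Benchmarks synthesise at 25 Hz (a 7-day recording is 15.1 M samples) and
train on five one-day synthetic participants — enough segment-posture
diversity that the forest generalises across participants rather than
memorising the handful of fixed segment orientations a smaller pool
offers, and sizes chosen so the full
suite and the acceptance script each run on a single CPU in a few minutes
while still exercising the complete 20,160-epoch week. Every stochastic
component takes an explicit integer seed; sub-streams derive
deterministically from it, and the full pipeline is bit-reproducible under
a fixed seed and config (verified by checksum in the test suite).

## Known limitations

- One recording per participant; no multi-deployment device management
  beyond donor calibration.
- Non-wear detection is SD-threshold only (no temperature or
  machine-learned variants).
- The hour-coverage criterion is read per-recording, not per-day; the
  alternative reading is a documented sensitivity, not implemented.
- Weekday/weekend summaries skip imputation, so they carry whatever
  diurnal wear bias the worn days have.
- The repeated-measures ANOVA and rank-based wear-time comparisons used in
  descriptive cohort tables are available through statsmodels/scipy
  directly and are not wrapped here.
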