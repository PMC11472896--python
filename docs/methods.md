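# Methods

## Scope and data model

`weartrial` models the accelerometer substudy of a two-arm, placebo-
controlled heart-failure trial programme run as two parallel trials split
by ejection fraction (Reduced: LVEF ≤ 40 %; Preserved: LVEF > 40 %) and
pooled for analysis. Patients wear a waist-mounted triaxial accelerometer
(100 Hz, units of g) for up to 7 days at three assessment periods —
baseline, week 8 and week 16 — and six daily activity outcomes are compared
between arms as changes from baseline.

The package's in-memory containers are thin dataclasses around numpy/pandas
objects: `RawAccelSignal` (one contiguous recording), `EpochSeries` (60-s
summaries), `DayValidity`/`PeriodValidity`, daily and period summary
DataFrames, and `EffectEstimate`.

## Signal processing

*Coordinates.* z is vertical (+1 g) when upright; this is the generator's
convention and the posture classifier's assumption.

*Gravity removal.* 4th-order Butterworth high-pass at 0.25 Hz, applied
forward–backward (`sosfiltfilt`) so the phase is zero and step-peak timing
is unbiased. 0.25 Hz is the standard actigraphy band edge between postural
orientation and movement. Constant input maps to exactly zero output; a
1.5 Hz gait component passes with < 5 % attenuation. Signals shorter than
10 s are rejected (filter warm-up).

*Counts.* One count equals 0.001664 g·s of rectified dynamic acceleration:
per epoch, counts = Σ‖a_dyn‖·Δt / 0.001664 over the triaxial dynamic
magnitude. Commercial count definitions are proprietary; this documented
constant puts brisk walking near 2000–7000 counts/min and makes outputs
exactly reproducible. Counts are linear in signal amplitude.

*Steps.* Peaks of the vertical dynamic axis with height ≥ 100 mg and a
0.25-s refractory period (`scipy.signal.find_peaks`), covering cadences up
to 4 Hz. One generator gait cycle produces one positive peak, so detected
steps can be compared exactly to generated truth (observed agreement ~0.1 %
on default days; the daily-summary contract is ± 2 %).

*Posture.* Standing iff the low-pass (0.25 Hz) vertical axis is ≥ 0.7 g —
a documented cone-about-vertical proxy for the device's classifier.

*Walking bouts.* Maximal runs of ≥ 3 steps, inter-step gaps ≤ 2.0 s, all
steps during standing. Non-standing steps break and are excluded from runs.

*Epoching.* Partial trailing epochs are dropped (warned), never padded,
to avoid diluting per-minute statistics.

## Wear validity

An epoch is nonwear iff it sits in a run of ≥ 60 consecutive minutes with
dynamic RMS < 3 mg; an off-body device reads an essentially constant
gravity vector, and the generator encodes nonwear as exactly constant
signal, making the rule's contract exact. A day is valid with ≥ 10 h of
wear epochs starting within the half-open clock window [06:00, 22:00); an
assessment period is eligible with ≥ 3 valid days of ≤ 7. Both thresholds
are inclusive, following the protocol's "≥" wording; whether the original
trial treated exactly 10.0 h as valid is not documented, so the inclusive
reading is a package decision. Local clock time only; no DST handling.

## Daily outcomes

- **steps** — all detected step events (bouted or not). Stair steps are
  not modelled; the generator contains no stairs.
- **LVPA / MVPA hours** — worn epochs with METs ≥ 1.5 / ≥ 3.0 (inclusive),
  times epoch length. METs use the documented stand-in map
  mets = 1 + counts/1000 (counts/min per MET above rest), anchored at
  1.0 MET for zero counts and monotone in counts. The validated device
  algorithm is unpublished, so numerical agreement of absolute LVPA/MVPA
  levels with the device is not claimed — between-arm contrasts, which the
  trial analysis uses, are unaffected by monotone recalibration.
- **VMU (counts/min)** — mean over worn minutes of rectified vertical
  dynamic acceleration integrated per minute, times the count constant
  (the "root of the squared signal" of a scalar being its absolute value).
- **movement intensity during walking (mg)** — RMS of the *Euclidean
  magnitude* of the dynamic triaxial signal over the union of walking
  bouts. A literal arithmetic sum of the three axes is sign-cancelling and
  not an intensity measure, so the vector-magnitude reading is used and
  documented. Days without bouts report a missing value (never zero, which
  would conflate "no walking" with "infinitely light walking"); period
  averages skip missing days.
- **total counts (×10³)** — counts summed over worn epochs.

## Trial analysis

Valid days are averaged (arithmetic mean; missing-aware for walking
intensity) into one value per patient × period. The analysis cohort is the
complete-case paired set: patients with eligible baseline *and* week-16
periods; week-8 analyses use the subset of that cohort with week-8 data.
No imputation anywhere.

The ANCOVA regresses change on a treatment indicator (placebo reference)
plus baseline value of the outcome, LVEF, trial, age, sex, BMI, natural-log
NT-proBNP (right-skewed biomarker), NYHA class and region, the last two
dummy-coded against their most frequent level (any full-rank coding yields
the same arm coefficient). The trial term is dropped automatically in
single-trial cohorts. Fitting uses statsmodels OLS on an explicitly built
design matrix; the 95 % CI uses the t distribution on residual degrees of
freedom, appropriate at n ≈ 200. The interaction test adds arm × trial and
reports its Wald p-value. Rank-deficient designs raise an error naming the
collinear columns. Point estimates and CIs are equivariant under outcome
rescaling. p-values are computed but the reporting surface leads with CIs,
consistent with an exploratory, non-confirmatory analysis; no multiplicity
adjustment is applied. Display rounding: integers for steps, VMU, counts;
two decimals for hours and mg; JSON retains full precision.

## Synthetic-trial generator

*Covariates* reproduce the published baseline table: age ~ N(71, 9²), 32 %
female, BMI ~ N(29, 5²), LVEF ~ N(33, 5²) truncated ≤ 40 (Reduced, 36 % of
patients) or N(49, 7²) truncated > 40 (Preserved) — overall mean ≈ 43 % —
NT-proBNP log-normal (μ = ln 861, σ = 0.84, matching median 861 and IQR
514–1591), NYHA I/II/III = 8/84/8 %, and a 4-level region placeholder
(the real region categories are not published). Arm counts follow the
allocation ratio deterministically (211 patients at 107:104 reproduce those
counts exactly).

*Raw-signal path.* A day is 24 h at a configurable rate (device default
100 Hz; bulk tests run 5–20 Hz purely to keep whole-day simulation
tractable — every detector contract is rate-independent). Sedentary wear is
band-limited (< 2 Hz) Gaussian noise around the gravity vector (default
mean dynamic 6 mg); walking bouts are vertical sinusoids at the patient's
cadence (default 1.8 steps/s, 60-s bouts, 300 mg peaks, ± 20 % per-step
jitter, half-amplitude horizontal sway), one positive peak per step so true
steps are recorded exactly; off-body intervals are strictly constant.
Default wear is 06:30–21:30 (15 h in the protocol window); a configurable
fraction of days (default 10–25 % in tests) are short-wear days
(09:00–13:30), invalid by construction. Bout counts are Poisson with a
log-normal patient effect (SD 0.25 on the log scale); the default 40
bouts/day yields ≈ 4300 expected steps, a realistic heart-failure level
(the trial's own baseline activity level is not published). Secular drift
multiplies bout rates by 0.92 (week 8) and 0.82 (week 16), mirroring the
published placebo-arm decline in steps; the treatment effect multiplies
bout rate and walk amplitude from week 8 onward, sized per patient so the
week-16 arm difference in expected steps equals a configurable δ.
Missingness removes whole patient-periods completely at random — the
mechanism matching a complete-case estimand that stays unbiased.

*Outcome-level path.* Estimator calibration needs thousands of replicate
trials, which is not sensible through 100-Hz signal synthesis; the
outcome generator therefore samples patient × period summaries directly
from the additive Gaussian model the signal path targets: outcome = mean +
age slope + between-patient latent + period drift + injected arm effect +
residual (scaled by √(7/valid days)). Defaults put the change-from-baseline
SD near 2000 steps/day and 90 VMU counts/min — the published scale — with
week-16 placebo drift of −850 steps. Being exactly linear-Gaussian, the
path gives the ANCOVA its textbook exactness, so measured type-I error and
coverage test the implementation, not distributional luck. Values are not
truncated at zero; rare negative values are accepted to preserve exact
calibration semantics.

*What the generator does not emulate* — and hence what passing tests do not
establish about real data: stair and non-gait activity, device
misorientation and battery artefacts, informative (non-MCAR) dropout,
heavy-tailed or skewed outcome noise, within-week circadian structure
beyond the wear window, and the proprietary device algorithms (counts,
steps, METs, posture). The pipeline's *contracts* (thresholds, filters,
estimator) are exercised exactly; its *absolute* metric levels are tied to
this package's documented constants.

## Numerical and size choices

Oracle tests compare pipeline sums to independent brute-force sample sums
at 1e-12 relative (float-precision agreement; summation order differs) and
RMS quantities at 1e-9. The ANCOVA is checked against a normal-equations
solve at 1e-8. Monte-Carlo sizes: 2000 null replicates at n=200 for type-I
error (binomial SE ≈ 0.5 %, band 5 % ± 1 %) and 500 replicates at n=1000
with δ = 800 steps for recovery (bias tolerance 3 Monte-Carlo SEMs,
coverage band 93–97 %). End-to-end raw-signal runs use 10 patients × 3
periods × 4 days at 10 Hz — sizes chosen to exercise every rule (short-wear
days, missing periods, both arms) while keeping whole-day IIR filtering,
the pipeline's dominant cost, proportionate.

## Known limitations

- Absolute LVPA/MVPA and count levels are package conventions, not device
  reproductions; only monotone-invariant and between-arm quantities should
  be compared across implementations.
- The wear-validity window logic assumes epochs aligned to whole minutes of
  local time and days pre-split at midnight.
- The ANCOVA assumes homoscedastic errors; no robust/sandwich option is
  exposed.
- Transition epochs at wear/nonwear boundaries can leak ~1–2 min of
  apparent wear per boundary through filter ringing; day-validity decisions
  are robust to this unless a day sits within minutes of the 10-h line.
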