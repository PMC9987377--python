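# Methods

## The study the generator emulates

A single-arm, six-month remote observation of 40 ambulatory adults with
ALS. Each participant wears one of two devices continuously: a wrist
monitor producing minute-level activity counts (AC — a unitless magnitude
summary of the acceleration signal per 60 s epoch) with a vendor wear flag,
or an ankle monitor producing minute-level step sums with no epoch-level
wear indicator. Surveys are collected on a smartphone every 2–4 weeks
(self-entry ALSFRS-RSE and normed ROADS), and the staff-administered
ALSFRS-R is obtained at months 0, 3 and 6. The analysis sample keeps
participants with at least two complete submissions of each self-entry
instrument.

## Generative model

Every participant i carries a latent severity trajectory
`L_i(t) = l0_i + l1_i t` (t in months; `l0 ~ N(0, 1)`, `l1 ~ N(0, 0.15²)`
by default) plus stream-specific bivariate random effects. The three
observation streams are:

- **Surveys.** `score = β₀ + β₁ t + b0_i + b1_i t + λ L_i(t) + ε`, rounded
  to the integer scale and clipped to the admissible range (0–48 for
  ALSFRS; 0–146 for normed ROADS). The ALSFRS-R and ALSFRS-RSE share one
  random-effect pair (they measure the same construct, which also makes
  the stacked two-scale model correctly specified); the self-entry
  baseline is the staff baseline plus the self-report offset. Default
  fixed effects are the published estimates: ALSFRS-R 31.6 baseline,
  −0.37/month; ALSFRS-RSE slope −0.48/month with offset +2.86 (implying a
  34.46 self-entry baseline — the offset and the staff baseline define the
  self-entry line, so the marginal self-entry baseline is derived, not
  separately configurable); ROADS 84.9, −1.26/month.
- **Daily activity totals.** The same linear random-slope law on the
  natural outcome scale: wrist TAC baseline 1,362,438 counts/day declining
  58,631/month; ankle daily steps 1,871 declining 57.79/month. The latent
  severity enters *additively*, scaled by `latent_coupling` (counts or
  steps per severity unit). An additive, natural-scale coupling was chosen
  over a multiplicative (log-scale) one deliberately: it keeps the daily
  mean linear in time, so the linear mixed model the analysis fits is the
  true model and parameter recovery is a meaningful check rather than an
  approximation. Totals are floored at zero; default variance components
  are small enough relative to the means that this truncation is rare
  (≈1% of late-period days) and its bias is well inside Monte-Carlo noise
  at the default study size.
- **Minute grids.** Each day's total is spread over 1440 minutes
  proportionally to a circadian profile (raised cosine over 07:00–22:00
  waking hours above a small night floor; the ankle device gets a zero
  night floor because wearers remove it for sleep) multiplied by i.i.d.
  gamma "burst" weights (shape 0.6 for AC, 0.05 for steps — the latter
  tuned so a typical day has a few hundred stepping minutes and mean
  cadence near 9 steps/min). Integer minute values use largest-remainder
  apportionment, so minutes always add back to the rounded daily total.
  Wrist days then receive Poisson-many non-wear blocks (wear flag off,
  value 0 — an off-body device records nothing) with exponential lengths,
  and, with probability 0.1/day, one 4-hour charging gap of missing data.

RNG substreams are spawned from the master seed keyed by (participant
index, data stream) — profile, daily totals, minute grids and surveys each
consume their own stream — so adding a participant never changes another's
data, and generating at daily resolution yields byte-identical surveys and
daily totals to the minute-level run.
The within-day allocation model is a stand-in: the study design this
package emulates does not specify a within-day activity distribution, so
minute-level realism (fragmentation level, bout structure) should not be
read as a claim about any real cohort. What the synthetic data *does*
share with the real design is the daily-level trajectory law, the survey
schedule and noise structure, the missingness mechanisms, and the
device-specific measurement conventions — which is what the downstream
statistical machinery consumes. Passing tests therefore validate the
pipeline's correctness under the stated model, not device physics; the
generator also has no dropout/withdrawal process beyond missing minutes.

## Analysis conventions and numerical choices

- **Months** = days / 30.4375 (mean Gregorian month), so 6 months ≈ 182.6
  days.
- **Valid hours** are clock-aligned (minute-of-day blocks), not sliding
  60-minute windows; a valid day needs ≥8 valid hours.
- **Imputation donors** are the participant's valid days; a slot donates
  iff non-missing and wear-flagged. Non-wear minutes on valid days are
  treated as missing and imputed (this is what makes investigator-derived
  measures span 1440 minutes). A minute-of-day with no donor anywhere is
  filled with 0 and logged.
- **Fragmentation**: transitions are counted within a day only (no wrap
  across midnight); denominators count conditioning-state minutes among
  minutes 0..1438; a zero denominator yields a missing value, never 0. The
  active threshold (AC > 1853, strict) and the cadence band edges are
  config values with published defaults.
- **Cadence statistics** (mean/median/p95) are computed over minutes with
  ≥1 step; the separate percent-time bands treat zero-step minutes as
  non-activity, and vendor cadence summaries conventionally exclude them.
  The 95th percentile uses linear interpolation between order statistics.
  Percent-time denominators are minutes inside valid hours, not 1440 — the
  step device has no wear flag, and an all-day denominator would conflate
  non-wear with inactivity. Max consecutive cadences require full windows.
- **Mixed models** are fitted by REML (variance components feed R², and
  REML is the conventional default). The outcome is internally rescaled to
  unit SD before optimization — the optimizer fails its gradient check on
  count-scale outcomes (~10⁶) — and every reported quantity is
  back-transformed exactly. Optimizers are tried in the order lbfgs,
  powell, cg; a singular random-effect covariance triggers a diagonal-G
  refit that is flagged on the results object; fixed-effect CIs and
  p-values are Wald. Non-convergence is explicit (`converged=False`, and
  derived quantities raise), never silent.
- **R²**: marginal `R²m = σ²_f / (σ²_f + σ²_r + σ²_ε)` and conditional
  `R²c = (σ²_f + σ²_r) / (σ²_f + σ²_r + σ²_ε)`, where σ²_f is the variance
  of the fixed-effect linear predictor over the observed design and σ²_r
  is the observation-averaged `z'Gz` (the random-slope extension; with a
  random slope the random-effect variance is observation-dependent).
- **≥10% relative change** is evaluated on model conditional means
  (fixed + predicted random effects) at t = 0 and t = 6 exactly;
  participants must also match the sign of the population slope;
  zero-baseline participants are excluded.
- **Matched correlations**: staff administrations are labelled by the
  nearest of months 0/3/6; each pairs with the participant's self-entry
  score of minimal |date offset| ≤ 28 days, equidistant ties breaking
  toward the earlier survey (deterministic); Pearson r on integer scores
  without jitter; fewer than 3 pairs gives a missing r with a warning.
- **Association covariates**: window = survey date ±7 days inclusive
  (15 calendar days, chosen for symmetry); the mean is over available
  valid-day values, missing if none. Standardization is pooled across
  participants and timepoints with the n−1 SD. The association model's
  random slope is on the covariate (per-participant association
  heterogeneity) because time is not among these models' fixed effects.
  No multiple-testing correction; the composite criterion is p < 0.05 for
  both self-entry instruments.
- **Sensitivity scenarios** are 7-day blocks anchored at each
  participant's baseline day (not calendar weeks): keep the first wD weeks
  of every (wD+wB)-week cycle. Masking applies after validity filtering —
  the experiment emulates *not collecting*, so wear behavior within
  retained weeks is unchanged. Participants left with <2 days are dropped
  with a log message.

## Problem sizes in the test and acceptance runs

Replicate studies (parameter recovery, CI coverage, scenario sensitivity)
run the generator at daily resolution: the minute-level path preserves
daily totals by construction (largest-remainder apportionment), so the
daily trajectory law — the only thing the replicate fits consume — is
identical, and 200 cohorts of 40×180 days fit in minutes. Recovery uses
200 replicates, sensitivity 100, and oracle-equivalence checks 1000 random
days; one full minute-level cohort (40 participants × 180 days × 1440
minutes) exercises the complete validity → imputation → measures → models
chain.

## Known limitations

- Vendor-proprietary daily measures (light/moderate/vigorous minutes,
  calories, METs, sleep) and the raw-accelerometry → AC conversion are out
  of scope; the wear flag is taken as input, not re-derived.
- The imputation is the minute-of-day donor-mean scheme only; no
  model-based or cross-participant imputation.
- Residuals are homoscedastic and serially independent within participant;
  no autocorrelated error structures or non-Gaussian outcomes.
- Survey scores are rounded to integers by default, which perturbs
  noiseless "exact recovery" checks; the generator exposes
  `round_scores=False` for those.
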