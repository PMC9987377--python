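# alswear

Longitudinal analysis of wearable-device and smartphone-survey data for
tracking ALS (amyotrophic lateral sclerosis) progression, with a synthetic
cohort generator that emulates a six-month remote digital-phenotyping study:
40 ambulatory adults wearing either a wrist activity monitor (minute-level
activity counts, AC) or an ankle step monitor (minute-level step sums), and
completing self-entry functional surveys — the ALSFRS-RSE (self-entry
revised ALS Functional Rating Scale, 0–48) and the normed ROADS
(Rasch-built Overall ALS Disability Scale) — every 2–4 weeks, with the
staff-administered ALSFRS-R at months 0, 3 and 6.

The package is for biostatisticians and digital-outcome researchers who want
a tested, reproducible implementation of this analysis stack:

- **Wear validity**: device-specific valid hours (wrist: 60 worn,
  non-missing minutes in a clock hour; ankle: ≥1 step logged in the hour)
  and valid days (≥8 valid hours), plus the compliance summary table.
- **Imputation**: each minute lacking an observed worn AC on a valid day is
  filled with the participant's mean observed AC at that minute-of-day
  across their valid days, so investigator-derived daily measures always
  span 1440 analyzable minutes.
- **Daily measures**: total activity counts `TAC = Σ_m AC_m`,
  `log(TAC + 1)`, `Σ_m log(AC_m + 1)`, active/sedentary minutes
  (active ⟺ AC > 1853), the fragmentation measures
  `ASTP = P(sedentary_{m+1} | active_m)` and
  `SATP = P(active_{m+1} | sedentary_m)`; and the step-device measures
  (total steps; mean/median/95th-percentile cadence over stepping minutes;
  percent time at 1–15, 16–40, 41+ steps/minute; max consecutive 60/20/5/1-
  minute cadences; peak performance index = mean of the 30 most intensive
  non-contiguous minutes).
- **Models**: random intercept + random slope linear mixed models fitted by
  REML,

  `y_ij = β₀ + β₁ t_ij + x_ij'γ + b0_i + b1_i t_ij + ε_ij`,
  `(b0_i, b1_i) ~ N(0, G)`, `ε_ij ~ N(0, σ²)`,

  with Wald 95% CIs, marginal/conditional R² (Nakagawa–Schielzeth with the
  observation-averaged z'Gz random-slope extension), per-participant
  conditional means (empirical BLUPs) and the percentage of participants
  with ≥10% relative conditional-mean change over 6 months in the
  population direction.
- **Survey comparisons**: per-instrument trajectory models, the stacked
  ALSFRS model with a self-entry indicator (+2.86-point baseline offset)
  and indicator×time interaction, device-group models, and matched Pearson
  correlations pairing each staff ALSFRS-R with the closest self-entry
  score within ±28 days.
- **Associations**: survey score ~ standardized 15-day window mean of each
  daily measure, with a per-participant random slope on the covariate.
- **Monitoring-frequency sensitivity**: re-fitting the TAC trajectory under
  cyclic wD-weeks-on / wB-weeks-off collection schedules.

## Worked example

```python
from alswear import CohortConfig, generate_cohort, filter_valid_days, \
    impute_cohort, derive_all, fit_trajectory_models
from alswear.pipeline import fit_daily_measure_models

cfg = CohortConfig(master_seed=7)          # defaults = published estimates
cohort = generate_cohort(cfg)              # 40 participants, 180 days
valid, validity = filter_valid_days(cohort.grids)
imputed = impute_cohort(valid)
daily = derive_all(imputed, [g for g in valid if g.device == "modus"])

fits = fit_trajectory_models(cohort.surveys)
print(fits["ALSFRS_RSE"].summary())
```

prints (seed 7):

```
Random-slope LMM: score (REML; n_obs=268, n_participants=40)
converged=True

term                        estimate        ci_low       ci_high         p
Intercept                       34.4         32.82         35.99         0
t_months                     -0.4199       -0.5845       -0.2553  5.76e-07

random effects: sd(intercept)=5.007, sd(slope)=0.4182, corr=0.002
residual sd=1.449
R2m=0.020, R2c=0.929
```

i.e. the self-entry ALSFRS starts near 34.4 points and declines by about
0.42 points/month in this simulated cohort (truth 34.46 and −0.48; both
inside the intervals), with 93% of score variance explained once
participant-specific trajectories are included. Fitting the daily TAC table
the same way,

```python
print(fit_daily_measure_models(daily, measures=["tac"])
      [["baseline_est", "slope_est", "r2c", "pct_rel_change_6m"]])
```

gives a baseline near 1.40M counts/day declining by ≈56k counts/month
(this seed's realized cohort truth: 1.42M and −65k; R²c 0.83), with 80% of
participants showing a ≥10% six-month relative decline.

There is also a CLI over the same stages:

```bash
alswear simulate --seed 7 --out-dir out/
alswear all --seed 7 --out-dir out/      # full pipeline + manifest
```

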