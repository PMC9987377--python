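"""Cohort and pipeline configuration.

All simulation truths and analysis constants live here, with defaults set to
the published cohort's estimates: survey baselines/slopes (ALSFRS-R 31.6,
-0.37/month; ALSFRS-RSE slope -0.48/month with a +2.86-point self-entry
offset; normed ROADS 84.9, -1.26/month), the investigator-derived total
activity counts trajectory (baseline 1,362,438 counts/day declining by
58,631/month), the active-minute threshold (AC > 1853) and the Modus cadence
bands (1-15 / 16-40 / 41+ steps per minute).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import yaml

#: Mean Gregorian month length in days; "monthly" slopes use this convention.
DAYS_PER_MONTH = 30.4375

#: Minutes in a day; every minute grid has exactly this many slots.
MINUTES_PER_DAY = 1440

ACTIGRAPH = "actigraph"
MODUS = "modus"

ALSFRS_R = "ALSFRS_R"
ALSFRS_RSE = "ALSFRS_RSE"
ROADS = "ROADS"
INSTRUMENTS = (ALSFRS_R, ALSFRS_RSE, ROADS)


class ConfigError(ValueError):
    """A configuration field violates its constraints; names the field."""


class DataIntegrityError(ValueError):
    """Input records are mutually inconsistent (e.g. mixed devices)."""


@dataclass
class RandomEffects:
    """Bivariate random intercept/slope law: SDs and their correlation."""

    intercept_sd: float
    slope_sd: float
    corr: float = 0.0

    def validate(self, name: str) -> None:
        if self.intercept_sd < 0 or self.slope_sd < 0:
            raise ConfigError(f"{name}: random-effect SDs must be >= 0")
        if not -1.0 <= self.corr <= 1.0:
            raise ConfigError(f"{name}.corr must be in [-1, 1]")

    def covariance(self):
        import numpy as np

        off = self.corr * self.intercept_sd * self.slope_sd
        return np.array(
            [[self.intercept_sd**2, off], [off, self.slope_sd**2]]
        )


@dataclass
class SurveyParams:
    """Fixed effects, noise and range for the three instruments.

    The ALSFRS-R and ALSFRS-RSE share one participant-level random
    intercept/slope (they measure the same construct); the self-entry version
    adds `self_report_offset` points to the staff-administered baseline and
    carries its own population slope. ROADS is simulated directly on its
    normed scale with its own random effects.
    """

    alsfrs_r_baseline: float = 31.6
    alsfrs_r_slope: float = -0.37  # points / month
    alsfrs_rse_slope: float = -0.48
    self_report_offset: float = 2.86  # RSE baseline minus ALSFRS-R baseline
    roads_baseline: float = 84.9
    roads_slope: float = -1.26

    alsfrs_re: RandomEffects = field(
        default_factory=lambda: RandomEffects(5.0, 0.25)
    )
    roads_re: RandomEffects = field(
        default_factory=lambda: RandomEffects(13.0, 0.60)
    )

    alsfrs_r_residual_sd: float = 1.5
    alsfrs_rse_residual_sd: float = 1.5
    roads_residual_sd: float = 4.0

    # points of score per unit of latent severity (intercept and slope alike)
    alsfrs_latent_loading: float = 2.0
    roads_latent_loading: float = 5.0

    alsfrs_range: tuple[float, float] = (0.0, 48.0)
    roads_range: tuple[float, float] = (0.0, 146.0)

    #: instruments are integer-scored; disable for exact-recovery checks
    round_scores: bool = True

    def baseline(self, instrument: str) -> float:
        if instrument == ALSFRS_R:
            return self.alsfrs_r_baseline
        if instrument == ALSFRS_RSE:
            return self.alsfrs_r_baseline + self.self_report_offset
        if instrument == ROADS:
            return self.roads_baseline
        raise ConfigError(f"unknown instrument {instrument!r}")

    def slope(self, instrument: str) -> float:
        return {
            ALSFRS_R: self.alsfrs_r_slope,
            ALSFRS_RSE: self.alsfrs_rse_slope,
            ROADS: self.roads_slope,
        }[instrument]

    def residual_sd(self, instrument: str) -> float:
        return {
            ALSFRS_R: self.alsfrs_r_residual_sd,
            ALSFRS_RSE: self.alsfrs_rse_residual_sd,
            ROADS: self.roads_residual_sd,
        }[instrument]

    def score_range(self, instrument: str) -> tuple[float, float]:
        return self.roads_range if instrument == ROADS else self.alsfrs_range

    def validate(self) -> None:
        self.alsfrs_re.validate("surveys.alsfrs_re")
        self.roads_re.validate("surveys.roads_re")
        for nm in ("alsfrs_r", "alsfrs_rse", "roads"):
            if getattr(self, f"{nm}_residual_sd") < 0:
                raise ConfigError(f"surveys.{nm}_residual_sd must be >= 0")
        for nm in ("alsfrs_range", "roads_range"):
            lo, hi = getattr(self, nm)
            if not lo < hi:
                raise ConfigError(f"surveys.{nm} must satisfy lo < hi")


@dataclass
class ActivityParams:
    """Daily activity-volume trajectory for one device type.

    `baseline`/`slope` are the population fixed effects of the daily total
    (activity counts for the wrist device, steps for the ankle device);
    participant heterogeneity comes from `re` plus the shared latent-severity
    trajectory scaled by `latent_coupling` (outcome units per severity unit).
    `residual_sd` is day-to-day noise around a participant's line.
    """

    baseline: float
    slope: float  # units / month
    re: RandomEffects
    residual_sd: float
    latent_coupling: float
    # within-day allocation: gamma burstiness of minute weights
    minute_gamma_shape: float

    def validate(self, name: str) -> None:
        self.re.validate(f"{name}.re")
        if self.residual_sd < 0:
            raise ConfigError(f"{name}.residual_sd must be >= 0")
        if self.minute_gamma_shape <= 0:
            raise ConfigError(f"{name}.minute_gamma_shape must be > 0")


def _default_actigraph_activity() -> ActivityParams:
    return ActivityParams(
        baseline=1_362_438.0,
        slope=-58_631.0,
        re=RandomEffects(300_000.0, 25_000.0),
        residual_sd=200_000.0,
        latent_coupling=150_000.0,
        minute_gamma_shape=0.6,
    )


def _default_modus_activity() -> ActivityParams:
    return ActivityParams(
        baseline=1_871.0,
        slope=-57.79,
        re=RandomEffects(800.0, 35.0),
        residual_sd=300.0,
        latent_coupling=150.0,
        minute_gamma_shape=0.05,
    )


@dataclass
class MissingnessParams:
    """Non-wear and charging gaps on the wrist-device minute stream."""

    nonwear_blocks_mean: float = 1.0  # Poisson mean blocks / day
    nonwear_block_minutes_mean: float = 90.0
    nonwear_block_minutes_min: int = 15
    nonwear_block_minutes_max: int = 480
    charging_gap_prob: float = 0.10  # per day
    charging_gap_minutes: int = 240

    def validate(self) -> None:
        if self.nonwear_blocks_mean < 0:
            raise ConfigError("missingness.nonwear_blocks_mean must be >= 0")
        if not 0 <= self.charging_gap_prob <= 1:
            raise ConfigError("missingness.charging_gap_prob must be in [0, 1]")
        if not (
            0
            < self.nonwear_block_minutes_min
            <= self.nonwear_block_minutes_max
            <= MINUTES_PER_DAY
        ):
            raise ConfigError("missingness.nonwear block length bounds invalid")
        if not 0 <= self.charging_gap_minutes <= MINUTES_PER_DAY:
            raise ConfigError(
                "missingness.charging_gap_minutes must be in [0, 1440]"
            )


@dataclass
class CircadianParams:
    """Within-day activity profile: a waking-hours bump over a low night floor."""

    wake_start_minute: int = 420  # 07:00
    wake_end_minute: int = 1320  # 22:00
    night_level: float = 0.02

    def validate(self) -> None:
        if not 0 <= self.wake_start_minute < self.wake_end_minute <= MINUTES_PER_DAY:
            raise ConfigError(
                "circadian wake window must satisfy 0 <= start < end <= 1440"
            )
        if self.night_level < 0:
            raise ConfigError("circadian.night_level must be >= 0")


@dataclass
class CohortConfig:
    """Everything the generator and pipeline need, with published defaults."""

    n_participants: int = 40
    observation_days: int = 180
    device_split: float = 0.5  # fraction assigned the wrist (ActiGraph-like) device
    start_date: date = date(2021, 1, 4)

    survey_interval_days: tuple[int, int] = (14, 28)
    survey_completion_prob: float = 0.7
    staff_visit_months: tuple[float, ...] = (0.0, 3.0, 6.0)

    surveys: SurveyParams = field(default_factory=SurveyParams)
    actigraph_activity: ActivityParams = field(
        default_factory=_default_actigraph_activity
    )
    modus_activity: ActivityParams = field(default_factory=_default_modus_activity)

    # latent severity trajectory l0 + l1 * t shared by surveys and activity
    latent_intercept_sd: float = 1.0
    latent_slope_sd: float = 0.15

    missingness: MissingnessParams = field(default_factory=MissingnessParams)
    circadian: CircadianParams = field(default_factory=CircadianParams)

    # analysis constants
    active_threshold: float = 1853.0  # minute AC strictly above => active
    valid_hours_per_day: int = 8
    cadence_low_band: tuple[int, int] = (1, 15)
    cadence_medium_band: tuple[int, int] = (16, 40)
    cadence_high_min: int = 41

    master_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.observation_days < 1:
            raise ConfigError("observation_days must be >= 1")
        if not 0.0 <= self.device_split <= 1.0:
            raise ConfigError("device_split must be in [0, 1]")
        lo, hi = self.survey_interval_days
        if not 0 < lo <= hi:
            raise ConfigError("survey_interval_days must satisfy 0 < lo <= hi")
        if not 0 <= self.survey_completion_prob <= 1:
            raise ConfigError("survey_completion_prob must be in [0, 1]")
        if self.latent_intercept_sd < 0 or self.latent_slope_sd < 0:
            raise ConfigError("latent severity SDs must be >= 0")
        if self.valid_hours_per_day < 0 or self.valid_hours_per_day > 24:
            raise ConfigError("valid_hours_per_day must be in [0, 24]")
        if self.active_threshold < 0:
            raise ConfigError("active_threshold must be >= 0")
        self.surveys.validate()
        self.actigraph_activity.validate("actigraph_activity")
        self.modus_activity.validate("modus_activity")
        self.missingness.validate()
        self.circadian.validate()

    def activity(self, device: str) -> ActivityParams:
        if device == ACTIGRAPH:
            return self.actigraph_activity
        if device == MODUS:
            return self.modus_activity
        raise ConfigError(f"unknown device {device!r}")

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["start_date"] = self.start_date.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        if isinstance(d.get("start_date"), str):
            d["start_date"] = date.fromisoformat(d["start_date"])
        for key, sub in (
            ("surveys", SurveyParams),
            ("missingness", MissingnessParams),
            ("circadian", CircadianParams),
        ):
            if isinstance(d.get(key), dict):
                d[key] = _build(sub, d[key])
        for key in ("actigraph_activity", "modus_activity"):
            if isinstance(d.get(key), dict):
                d[key] = _build(ActivityParams, d[key])
        for key in ("survey_interval_days", "staff_visit_months",
                    "cadence_low_band", "cadence_medium_band"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _build(cls, d: dict):
    d = dict(d)
    for k, v in d.items():
        if isinstance(v, dict) and (k == "re" or k.endswith("_re")):
            d[k] = RandomEffects(**v)
        elif isinstance(v, list):
            d[k] = tuple(v)
    return cls(**d)
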