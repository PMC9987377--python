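"""Wear-compliance classification: valid hours, valid days, compliance table.

A valid day has at least 8 (not necessarily consecutive) valid hours. Valid
hours are device-specific: for the wrist device a clock hour is valid when
all 60 minutes are non-missing and wear-flagged; for the ankle step device an
hour is valid when at least one step was logged in it. Only valid days feed
any downstream wearable computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd

from .config import ACTIGRAPH, ALSFRS_RSE, MODUS, ROADS, DataIntegrityError
from .grids import MinuteDayGrid

DEFAULT_MIN_VALID_HOURS = 8


@dataclass
class DayValidity:
    participant_id: str
    date: Date
    device: str
    valid_hour_flags: np.ndarray  # 24 booleans
    min_valid_hours: int = DEFAULT_MIN_VALID_HOURS

    @property
    def valid_hour_count(self) -> int:
        return int(self.valid_hour_flags.sum())

    @property
    def is_valid_day(self) -> bool:
        return self.valid_hour_count >= self.min_valid_hours


def actigraph_valid_hours(
    day: MinuteDayGrid, min_valid_hours: int = DEFAULT_MIN_VALID_HOURS
) -> DayValidity:
    """An hour is valid iff all 60 minutes are worn and non-missing."""
    if day.device != ACTIGRAPH:
        raise DataIntegrityError(
            f"{day.participant_id}: actigraph_valid_hours on {day.device} day"
        )
    ok = (day.wear & ~day.missing).reshape(24, 60)
    return DayValidity(
        day.participant_id, day.date, day.device, ok.all(axis=1),
        min_valid_hours,
    )


def modus_valid_hours(
    day: MinuteDayGrid, min_valid_hours: int = DEFAULT_MIN_VALID_HOURS
) -> DayValidity:
    """An hour is valid iff at least one step was logged within it."""
    if day.device != MODUS:
        raise DataIntegrityError(
            f"{day.participant_id}: modus_valid_hours on {day.device} day"
        )
    steps = np.nan_to_num(day.values, nan=0.0).reshape(24, 60)
    return DayValidity(
        day.participant_id, day.date, day.device,
        steps.sum(axis=1) >= 1, min_valid_hours,
    )


def day_validity(
    day: MinuteDayGrid, min_valid_hours: int = DEFAULT_MIN_VALID_HOURS
) -> DayValidity:
    fn = actigraph_valid_hours if day.device == ACTIGRAPH else modus_valid_hours
    return fn(day, min_valid_hours)


def filter_valid_days(
    grids: list[MinuteDayGrid],
    min_valid_hours: int = DEFAULT_MIN_VALID_HOURS,
) -> tuple[list[MinuteDayGrid], pd.DataFrame]:
    """Keep only valid days; return them plus a validity table for all days.

    Raises
    ------
    DataIntegrityError
        If one participant appears with more than one device type.
    """
    devices: dict[str, str] = {}
    rows = []
    kept: list[MinuteDayGrid] = []
    for g in grids:
        prev = devices.setdefault(g.participant_id, g.device)
        if prev != g.device:
            raise DataIntegrityError(
                f"{g.participant_id}: mixed device types ({prev}, {g.device})"
            )
        v = day_validity(g, min_valid_hours)
        rows.append(
            {
                "participant_id": g.participant_id,
                "date": g.date,
                "device": g.device,
                "valid_hour_count": v.valid_hour_count,
                "is_valid_day": v.is_valid_day,
            }
        )
        if v.is_valid_day:
            kept.append(g)
    table = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "date", "device",
            "valid_hour_count", "is_valid_day",
        ],
    )
    return kept, table


def _median_range(x: pd.Series) -> dict[str, float]:
    x = x.dropna()
    if x.empty:
        return {"median": np.nan, "min": np.nan, "max": np.nan}
    return {
        "median": float(x.median()),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def compliance_summary(
    validity: pd.DataFrame, surveys: pd.DataFrame
) -> pd.DataFrame:
    """Per-device-group and combined compliance aggregates.

    One row per (metric, group) with the participant-level median, min and
    max of: complete self-entry ALSFRS submissions, ROADS submissions, days
    in the observation period (inclusive first-to-last day with device
    data), valid days, and the average number of valid hours on a valid day
    (missing for a participant with no valid day).
    """
    if validity.empty:
        raise ValueError("validity table is empty")
    per = []
    for pid, sub in validity.groupby("participant_id"):
        dates = pd.to_datetime(sub["date"])
        valid = sub[sub["is_valid_day"]]
        per.append(
            {
                "participant_id": pid,
                "device": sub["device"].iloc[0],
                "days_in_observation": (dates.max() - dates.min()).days + 1,
                "valid_days": int(sub["is_valid_day"].sum()),
                "avg_valid_hours": (
                    float(valid["valid_hour_count"].mean())
                    if len(valid)
                    else np.nan
                ),
            }
        )
    per_df = pd.DataFrame(per).set_index("participant_id")

    counts = (
        surveys[surveys["instrument"].isin([ALSFRS_RSE, ROADS])]
        .groupby(["participant_id", "instrument"])
        .size()
        .unstack(fill_value=0)
    )
    for inst, col in ((ALSFRS_RSE, "alsfrs_rse_submissions"),
                      (ROADS, "roads_submissions")):
        per_df[col] = (
            counts[inst].reindex(per_df.index).fillna(0).astype(int)
            if inst in counts
            else 0
        )

    metrics = [
        ("alsfrs_rse_submissions", "ALSFRS-RSE submissions"),
        ("roads_submissions", "ROADS submissions"),
        ("days_in_observation", "Days in observation period"),
        ("valid_days", "Valid days in observation period"),
        ("avg_valid_hours", "Average valid hours on a valid day"),
    ]
    rows = []
    groups = [(ACTIGRAPH, per_df[per_df["device"] == ACTIGRAPH]),
              (MODUS, per_df[per_df["device"] == MODUS]),
              ("combined", per_df)]
    for col, label in metrics:
        for gname, gdf in groups:
            if gdf.empty:
                continue
            rows.append(
                {"metric": label, "group": gname, **_median_range(gdf[col])}
            )
    return pd.DataFrame(rows)
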