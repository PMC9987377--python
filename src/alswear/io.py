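"""CSV dialects for every artifact the pipeline reads or writes.

All tables are long (tidy) format, dates ISO-8601, missing values encoded as
empty fields. Minute-level files have one row per participant-minute with
columns participant_id, date, minute_of_day (0-1439), value, wear, missing
(wear empty for ankle-device rows); imputed files add an `imputed` column.
"""

from __future__ import annotations

from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ACTIGRAPH, MINUTES_PER_DAY, MODUS
from .grids import GridStructureError, ImputedDayGrid, MinuteDayGrid


class MalformedFileError(ValueError):
    """A CSV row cannot be parsed; message names the file and row."""


def _parse_dates(series: pd.Series, path) -> pd.Series:
    try:
        return pd.to_datetime(series, format="ISO8601").dt.date
    except (ValueError, TypeError) as exc:
        bad = None
        for i, v in series.items():
            try:
                pd.to_datetime(v, format="ISO8601")
            except (ValueError, TypeError):
                bad = i
                break
        raise MalformedFileError(
            f"{path}: bad ISO-8601 date at data row {bad}: "
            f"{series.get(bad)!r}"
        ) from exc


def write_minute_csv(grids: list[MinuteDayGrid], path: str | Path) -> None:
    frames = []
    for g in grids:
        df = pd.DataFrame(
            {
                "participant_id": g.participant_id,
                "date": g.date.isoformat(),
                "minute_of_day": np.arange(MINUTES_PER_DAY),
                "value": g.values,
                "wear": (
                    g.wear.astype(int) if g.wear is not None else pd.NA
                ),
                "missing": g.missing.astype(int),
            }
        )
        if isinstance(g, ImputedDayGrid):
            df["imputed"] = g.imputed.astype(int)
        df.loc[g.missing, "value"] = pd.NA
        frames.append(df)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=[
            "participant_id", "date", "minute_of_day",
            "value", "wear", "missing",
        ]
    )
    out.to_csv(path, index=False)


def read_minute_csv(path: str | Path) -> list[MinuteDayGrid]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if df.empty:
        return []
    df["date"] = _parse_dates(df["date"], path)
    imputed_file = "imputed" in df.columns
    grids = []
    for (pid, day), sub in df.groupby(["participant_id", "date"], sort=True):
        sub = sub.sort_values("minute_of_day")
        if len(sub) != MINUTES_PER_DAY or not np.array_equal(
            sub["minute_of_day"].to_numpy(), np.arange(MINUTES_PER_DAY)
        ):
            raise GridStructureError(
                f"{path}: {pid} {day} does not have minutes 0..1439"
            )
        wear_col = sub["wear"]
        has_wear = wear_col.notna().all()
        device = ACTIGRAPH if has_wear else MODUS
        kwargs = dict(
            participant_id=pid,
            date=day,
            device=device,
            values=sub["value"].to_numpy(float),
            missing=sub["missing"].to_numpy(float).astype(bool),
            wear=wear_col.to_numpy(float).astype(bool) if has_wear else None,
        )
        if imputed_file and device == ACTIGRAPH:
            grids.append(
                ImputedDayGrid(
                    **kwargs, imputed=sub["imputed"].to_numpy(float).astype(bool)
                )
            )
        else:
            grids.append(MinuteDayGrid(**kwargs))
    return grids


def write_survey_csv(surveys: pd.DataFrame, path: str | Path) -> None:
    out = surveys.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.date.map(Date.isoformat)
    out.to_csv(path, index=False)


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    if df.empty:
        return df
    df["date"] = _parse_dates(df["date"], path)
    return df


def write_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.date.map(Date.isoformat)
    out.to_csv(path, index=False)


def read_table_csv(path: str | Path, date_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "participant_id" in df.columns:
        df["participant_id"] = df["participant_id"].astype(str)
    for c in date_cols:
        if c in df.columns and not df.empty:
            df[c] = _parse_dates(df[c], path)
    return df
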