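"""Minute-resolution day grids.

A `MinuteDayGrid` is one participant-day: 1440 slots of (value, wear,
missing), slot 0 at local midnight. The wrist device records activity counts
with an explicit wear flag; the ankle device records minute step sums and has
no epoch-level wear indicator (``wear is None``). Missing slots (charging,
upload gaps) carry NaN values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date

import numpy as np

from .config import ACTIGRAPH, MINUTES_PER_DAY, MODUS


class GridStructureError(ValueError):
    """A grid does not have exactly 1440 well-formed slots."""


@dataclass
class MinuteDayGrid:
    participant_id: str
    date: Date
    device: str  # "actigraph" | "modus"
    values: np.ndarray  # float, NaN where missing
    missing: np.ndarray  # bool
    wear: np.ndarray | None = None  # bool for actigraph, None for modus

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.values.shape != (MINUTES_PER_DAY,):
            raise GridStructureError(
                f"{self.participant_id} {self.date}: expected 1440 value "
                f"slots, got {self.values.shape}"
            )
        if self.missing.shape != (MINUTES_PER_DAY,):
            raise GridStructureError(
                f"{self.participant_id} {self.date}: missing flags must have "
                "1440 slots"
            )
        if self.device == ACTIGRAPH:
            if self.wear is None:
                raise GridStructureError(
                    "actigraph grids require a wear flag array"
                )
            self.wear = np.asarray(self.wear, dtype=bool)
            if self.wear.shape != (MINUTES_PER_DAY,):
                raise GridStructureError("wear flags must have 1440 slots")
        elif self.device == MODUS:
            self.wear = None
        else:
            raise GridStructureError(f"unknown device {self.device!r}")
        observed = self.values[~self.missing]
        if observed.size and np.nanmin(observed) < 0:
            raise GridStructureError("minute values must be >= 0")

    @property
    def observed_worn(self) -> np.ndarray:
        """Slots with an observed, device-worn value (donor-eligible)."""
        if self.device == MODUS:
            return ~self.missing
        return ~self.missing & self.wear


@dataclass
class ImputedDayGrid(MinuteDayGrid):
    """A wrist-device day after imputation: no missing values remain.

    `imputed` marks slots filled from the participant's donor-minute means;
    `values` at non-imputed slots are bit-identical to the source grid.
    """

    imputed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.imputed is None:
            raise GridStructureError("imputed flag array required")
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.imputed.shape != (MINUTES_PER_DAY,):
            raise GridStructureError("imputed flags must have 1440 slots")
        if np.isnan(self.values).any():
            raise GridStructureError("imputed grids must have no NaN values")
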