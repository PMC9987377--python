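"""Minute-level imputation of the wrist-device activity-count stream.

Before investigator-derived daily measures are computed, every minute that
lacks an observed, device-worn activity count on a valid day is filled with
the participant's mean observed-worn count at that minute-of-day across
their valid days. The result is a day that always spans 1440 analyzable
minutes, so volume measures are not biased downward by non-wear.

Donor pool: the participant's valid days; a slot donates iff it is
non-missing and wear-flagged. A minute-of-day with no donor on any valid day
is filled with 0 and a warning is logged.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import ACTIGRAPH, MINUTES_PER_DAY, DataIntegrityError
from .grids import ImputedDayGrid, MinuteDayGrid

logger = logging.getLogger(__name__)


def donor_minute_means(grids: list[MinuteDayGrid]) -> np.ndarray:
    """Per-minute-of-day mean of observed worn counts across the given days.

    Minutes with zero donors get 0.0 (logged).
    """
    values = np.stack([np.nan_to_num(g.values, nan=0.0) for g in grids])
    donors = np.stack([g.observed_worn for g in grids])
    counts = donors.sum(axis=0)
    sums = (values * donors).sum(axis=0)
    means = np.zeros(MINUTES_PER_DAY)
    has = counts > 0
    means[has] = sums[has] / counts[has]
    if (~has).any():
        logger.warning(
            "%s: %d minute-of-day slots have no donor on any valid day; "
            "imputing 0",
            grids[0].participant_id,
            int((~has).sum()),
        )
    return means


def impute_participant(grids: list[MinuteDayGrid]) -> list[ImputedDayGrid]:
    """Impute all of one participant's valid wrist-device days.

    Observed worn values pass through bit-identical; every other slot is
    filled with the donor-minute mean and flagged ``imputed``. Idempotent:
    already-imputed slots re-derive to the same donor means.
    """
    if not grids:
        raise ValueError("impute_participant requires at least one valid day")
    pids = {g.participant_id for g in grids}
    if len(pids) > 1:
        raise DataIntegrityError(f"multiple participants in one call: {pids}")
    if any(g.device != ACTIGRAPH for g in grids):
        raise DataIntegrityError(
            "imputation applies only to the actigraph activity-count stream"
        )
    means = donor_minute_means(grids)
    out = []
    for g in grids:
        fill = ~g.observed_worn
        values = np.where(fill, means, np.nan_to_num(g.values, nan=0.0))
        out.append(
            ImputedDayGrid(
                participant_id=g.participant_id,
                date=g.date,
                device=g.device,
                values=values,
                missing=g.missing.copy(),
                wear=g.wear.copy(),
                imputed=fill,
            )
        )
    return out


def impute_cohort(
    grids: list[MinuteDayGrid],
) -> list[ImputedDayGrid]:
    """Group valid actigraph days by participant and impute each."""
    by_pid: dict[str, list[MinuteDayGrid]] = {}
    for g in grids:
        if g.device == ACTIGRAPH:
            by_pid.setdefault(g.participant_id, []).append(g)
    out: list[ImputedDayGrid] = []
    for pid in sorted(by_pid):
        out.extend(impute_participant(by_pid[pid]))
    return out
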