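"""Wear/nonwear classification and the substudy's validity filter.

The trial protocol counts a day as valid when the device was worn for at
least 10 hours between 06:00 and 22:00, and an assessment period as eligible
when at least 3 of its 7 days are valid.  Thresholds are inclusive and the
clock window is half-open [06:00, 22:00), per the protocol's ">=" wording.

Nonwear itself must be inferred from the signal: an epoch is nonwear iff it
lies inside a run of at least 60 consecutive minutes whose dynamic RMS stays
below 3 mg — an off-body device reads an essentially constant gravity vector.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime

import numpy as np
import pandas as pd

from .signal_processing import EpochSeries

__all__ = [
    "DayValidity",
    "PeriodValidity",
    "detect_nonwear",
    "day_wear_hours",
    "period_eligibility",
    "NONWEAR_RMS_MG",
    "NONWEAR_RUN_MIN",
    "WINDOW_START_H",
    "WINDOW_END_H",
    "MIN_WEAR_HOURS",
    "MIN_VALID_DAYS",
]

NONWEAR_RMS_MG = 3.0      # dynamic RMS below this looks off-body
NONWEAR_RUN_MIN = 60      # minutes of sustained stillness required
WINDOW_START_H = 6        # protocol window 06:00 ..
WINDOW_END_H = 22         # .. 22:00 (exclusive)
MIN_WEAR_HOURS = 10.0     # inclusive
MIN_VALID_DAYS = 3        # inclusive, out of <= 7


@dataclass(frozen=True)
class DayValidity:
    """Validity of one calendar day of wear."""

    date: datetime.date
    wear_hours_in_window: float
    valid: bool


@dataclass(frozen=True)
class PeriodValidity:
    """Eligibility of one patient x assessment period."""

    patient_id: str
    period: str
    n_valid_days: int
    eligible: bool


def detect_nonwear(epochs: EpochSeries) -> EpochSeries:
    """Flag nonwear epochs in place and return the series.

    An epoch is nonwear iff it belongs to a run of >= NONWEAR_RUN_MIN
    consecutive epochs with ``dyn_rms_mg`` < NONWEAR_RMS_MG.  Requires at
    least one hour of epochs so the run rule can apply at all.
    """
    if len(epochs) * epochs.epoch_length < 3600:
        raise ValueError("need at least 1 h of epochs for nonwear detection")
    still = (epochs.data["dyn_rms_mg"].to_numpy() < NONWEAR_RMS_MG)
    run_len_needed = int(round(NONWEAR_RUN_MIN * 60 / epochs.epoch_length))

    wear = np.ones(len(still), dtype=bool)
    i = 0
    n = len(still)
    while i < n:
        if still[i]:
            j = i
            while j < n and still[j]:
                j += 1
            if j - i >= run_len_needed:
                wear[i:j] = False
            i = j
        else:
            i += 1
    epochs.data["wear"] = wear
    return epochs


def day_wear_hours(epochs: EpochSeries) -> DayValidity:
    """Wear hours inside [06:00, 22:00) and the day's validity flag.

    Counts wear epochs whose start lies in the window; the epochs must all
    belong to one calendar day (split multi-day series before calling).
    """
    starts = pd.DatetimeIndex(epochs.data["epoch_start"])
    days = np.unique(starts.date)
    if len(days) > 1:
        raise ValueError("epochs span multiple calendar days; split them first")
    in_window = (starts.hour >= WINDOW_START_H) & (starts.hour < WINDOW_END_H)
    wear = epochs.data["wear"].to_numpy(bool)
    hours = float(np.sum(in_window & wear)) * epochs.epoch_length / 3600.0
    return DayValidity(date=days[0], wear_hours_in_window=hours,
                       valid=hours >= MIN_WEAR_HOURS)


def period_eligibility(patient_id: str, period: str,
                       days: list[DayValidity]) -> PeriodValidity:
    """Eligible iff >= 3 of the period's <= 7 days are valid."""
    if len(days) > 7:
        raise ValueError("an assessment period holds at most 7 days")
    n_valid = sum(d.valid for d in days)
    return PeriodValidity(patient_id=patient_id, period=period,
                          n_valid_days=n_valid,
                          eligible=n_valid >= MIN_VALID_DAYS)
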