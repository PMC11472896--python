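"""The six daily physical-activity outcomes.

Per calendar day the pipeline reports:

- ``steps`` — total detected steps;
- ``lvpa_h`` / ``mvpa_h`` — hours of light-to-vigorous (>= 1.5 METs) and
  moderate-to-vigorous (>= 3.0 METs) activity over worn epochs;
- ``vmu_cpm`` — vector magnitude units: mean over worn minutes of vertical
  dynamic counts per minute;
- ``mi_walk_mg`` — movement intensity during walking: RMS of the dynamic
  triaxial vector magnitude over walking bouts, in mg;
- ``counts_k`` — total activity counts over worn epochs, in thousands.

METs come from a documented piecewise-linear map of counts (the validated
device algorithm is proprietary): mets = 1 + counts / MET_COUNT_SCALE, with
sedentary (zero-count) worn epochs anchored at exactly 1.0 MET.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signal_processing import COUNT_SCALE, EpochSeries, RawAccelSignal, WalkingBout

__all__ = [
    "estimate_mets",
    "time_in_bands",
    "compute_vmu",
    "movement_intensity_walking",
    "total_activity_counts",
    "summarize_day",
    "MET_COUNT_SCALE",
    "LVPA_MET_THRESHOLD",
    "MVPA_MET_THRESHOLD",
    "OUTCOME_COLUMNS",
]

#: Counts/min per MET above rest.  With the package's count constant a brisk
#: walk epoch (~2000-7000 counts/min) lands at >= 3.0 METs.
MET_COUNT_SCALE = 1000.0

LVPA_MET_THRESHOLD = 1.5   # nonsedentary activity, inclusive
MVPA_MET_THRESHOLD = 3.0   # brisk-walking intensity and above, inclusive

#: Vertical-axis count conversion reuses the single documented count constant.
VMU_COUNT_SCALE = COUNT_SCALE

OUTCOME_COLUMNS = ["steps", "lvpa_h", "mvpa_h", "vmu_cpm", "mi_walk_mg", "counts_k"]


def estimate_mets(epochs: EpochSeries) -> EpochSeries:
    """Fill per-epoch METs for worn epochs; nonwear epochs stay undefined.

    mets = 1.0 + counts / MET_COUNT_SCALE — monotone in counts and anchored
    at 1.0 MET for a zero-count epoch.
    """
    counts = epochs.data["counts"].to_numpy(float)
    mets = 1.0 + counts / MET_COUNT_SCALE
    mets = np.where(epochs.data["wear"].to_numpy(bool), mets, np.nan)
    epochs.data["mets"] = mets
    return epochs


def time_in_bands(epochs: EpochSeries) -> tuple[float, float]:
    """(LVPA hours, MVPA hours) over worn epochs; thresholds inclusive.

    MVPA is a subset of LVPA by construction.
    """
    wear = epochs.data["wear"].to_numpy(bool)
    mets = epochs.data["mets"].to_numpy(float)
    hours_per_epoch = epochs.epoch_length / 3600.0
    lvpa = float(np.sum(wear & (mets >= LVPA_MET_THRESHOLD))) * hours_per_epoch
    mvpa = float(np.sum(wear & (mets >= MVPA_MET_THRESHOLD))) * hours_per_epoch
    return lvpa, mvpa


def compute_vmu(epochs: EpochSeries) -> float:
    """Mean vertical counts per minute over worn minutes.

    Per-minute vertical counts are the rectified vertical dynamic signal
    integrated over the minute times the count constant (the square root of
    the squared vertical signal being its absolute value).  Returns NaN with
    zero worn minutes.
    """
    wear = epochs.data["wear"].to_numpy(bool)
    if not wear.any():
        return float("nan")
    per_min = (epochs.data["mean_abs_vertical_g"].to_numpy(float)
               * epochs.epoch_length * VMU_COUNT_SCALE)
    scale = 60.0 / epochs.epoch_length  # counts/epoch -> counts/min
    return float(np.mean(per_min[wear]) * scale)


def movement_intensity_walking(dynamic: np.ndarray, sig: RawAccelSignal,
                               bouts: list[WalkingBout]) -> float:
    """RMS dynamic vector magnitude over walking bouts, in mg.

    A day without walking bouts has no defined walking intensity and returns
    NaN (missing), never zero.
    """
    if not bouts:
        return float("nan")
    fs = sig.sampling_rate
    mask = np.zeros(sig.n_samples, dtype=bool)
    for b in bouts:
        i0 = int((b.start - sig.start_time).total_seconds() * fs)
        i1 = int(np.ceil((b.end - sig.start_time).total_seconds() * fs)) + 1
        mask[max(i0, 0):min(i1, sig.n_samples)] = True
    mag2 = np.sum(dynamic[mask] ** 2, axis=1)
    return float(np.sqrt(np.mean(mag2)) * 1000.0)


def total_activity_counts(epochs: EpochSeries) -> float:
    """Total counts over worn epochs, reported in thousands."""
    wear = epochs.data["wear"].to_numpy(bool)
    return float(epochs.data["counts"].to_numpy(float)[wear].sum() / 1000.0)


def summarize_day(epochs: EpochSeries, n_steps: int, bouts: list[WalkingBout],
                  dynamic: np.ndarray, sig: RawAccelSignal) -> pd.Series:
    """Assemble the six-outcome daily summary.

    An entirely nonwear day reports zero hours/counts and missing VMU and
    walking intensity, per each metric's own contract.
    """
    lvpa, mvpa = time_in_bands(epochs)
    return pd.Series({
        "steps": float(n_steps),
        "lvpa_h": lvpa,
        "mvpa_h": mvpa,
        "vmu_cpm": compute_vmu(epochs),
        "mi_walk_mg": movement_intensity_walking(dynamic, sig, bouts),
        "counts_k": total_activity_counts(epochs),
    })
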