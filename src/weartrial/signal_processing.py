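"""Raw triaxial acceleration → per-minute epoch summaries, steps, posture, bouts.

The device records waist-worn triaxial acceleration in units of g at 100 Hz.
This module removes the gravity component, summarizes the dynamic (gravity-
free) signal into fixed 60-s epochs, detects individual steps as peaks on the
vertical dynamic axis, classifies standing posture from the low-pass vertical
axis, and groups steps into walking bouts (>= 3 consecutive steps while
standing).

Coordinate convention: the z axis is vertical (reads +1 g) when the wearer is
upright.  All accelerations are in g unless a name says mg.

The commercial device's count definition, step detector and posture
classifier are proprietary; the operators here are documented, reproducible
stand-ins with fixed constants (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "RawAccelSignal",
    "EpochSeries",
    "StepEvent",
    "WalkingBout",
    "read_signal",
    "write_signal",
    "remove_gravity",
    "epoch_signal",
    "detect_steps",
    "detect_posture",
    "detect_walking_bouts",
    "COUNT_SCALE",
    "GRAVITY_CUTOFF_HZ",
    "STEP_PEAK_HEIGHT_G",
    "STEP_REFRACTORY_S",
    "CONSECUTIVE_STEP_GAP_S",
    "STANDING_VERTICAL_G",
]

#: One activity count corresponds to 0.001664 g*s of rectified dynamic
#: acceleration, so COUNT_SCALE converts g*s -> counts.  Chosen so brisk
#: walking lands near 2000-4000 counts/min.
COUNT_SCALE = 1.0 / 0.001664

#: High-pass band edge separating gravity/posture from movement (Hz).
GRAVITY_CUTOFF_HZ = 0.25

#: Minimum vertical dynamic peak accepted as a step (g).
STEP_PEAK_HEIGHT_G = 0.100

#: Minimum spacing between step peaks (s); caps detectable cadence at 4 Hz.
STEP_REFRACTORY_S = 0.25

#: Two steps are "consecutive" if separated by at most this gap (s).
CONSECUTIVE_STEP_GAP_S = 2.0

#: Low-pass vertical axis at or above this level (g) means standing upright.
STANDING_VERTICAL_G = 0.7

MIN_BOUT_STEPS = 3


@dataclass
class RawAccelSignal:
    """One contiguous recording of triaxial acceleration in g.

    Parameters
    ----------
    start_time
        Wall-clock time of the first sample.
    sampling_rate
        Samples per second; the trial device records at 100 Hz.
    samples
        ``(n, 3)`` float array of (x, y, z) acceleration in g.
    """

    start_time: pd.Timestamp
    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Seconds since start for each sample."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class EpochSeries:
    """Per-epoch (default 60 s) summaries of one signal.

    ``data`` columns:

    - ``epoch_start`` — timestamp of the epoch's first sample
    - ``mean_abs_vertical_g`` — mean |vertical dynamic acceleration| (g)
    - ``dyn_rms_mg`` — RMS of the dynamic vector magnitude (mg)
    - ``counts`` — activity counts (COUNT_SCALE * integral of rectified
      dynamic magnitude)
    - ``steps`` — detected steps starting in the epoch
    - ``standing_fraction`` — fraction of samples classified standing
    - ``wear`` — bool, filled by :mod:`weartrial.wear_validity`
    - ``mets`` — METs, filled by :mod:`weartrial.activity_metrics`
    """

    start_time: pd.Timestamp
    epoch_length: float
    data: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class StepEvent:
    """A single detected step (one accepted vertical peak)."""

    time: pd.Timestamp
    peak_accel_mg: float
    during_standing: bool


@dataclass(frozen=True)
class WalkingBout:
    """>= 3 consecutive steps taken during a standing period."""

    start: pd.Timestamp
    end: pd.Timestamp
    step_times: tuple
    n_steps: int

    def __post_init__(self) -> None:
        if self.n_steps < MIN_BOUT_STEPS:
            raise ValueError("a walking bout needs at least 3 steps")


# ---------------------------------------------------------------------------
# I/O — CSV dialect `time_s,x_g,y_g,z_g`
# ---------------------------------------------------------------------------

SIGNAL_COLUMNS = ["time_s", "x_g", "y_g", "z_g"]


def read_signal(path, start_time="2021-01-01 00:00:00") -> RawAccelSignal:
    """Read a raw signal CSV (`time_s,x_g,y_g,z_g`, one row per sample).

    The sampling rate is inferred from the median spacing of ``time_s``.
    Raises ``ValueError`` naming the first offending row for missing columns,
    non-monotone time, or non-finite samples.
    """
    df = pd.read_csv(path)
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"signal file {path} missing columns {missing}")
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("signal file must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"non-monotone time_s at row {row}")
    xyz = df[["x_g", "y_g", "z_g"]].to_numpy(float)
    bad = ~np.all(np.isfinite(xyz), axis=1)
    if bad.any():
        raise ValueError(f"non-finite acceleration at row {int(np.argmax(bad))}")
    fs = 1.0 / float(np.median(dt))
    return RawAccelSignal(start_time=pd.Timestamp(start_time), sampling_rate=fs,
                          samples=xyz)


def write_signal(sig: RawAccelSignal, path) -> None:
    """Write the CSV dialect read back losslessly by :func:`read_signal`."""
    df = pd.DataFrame({
        "time_s": sig.times(),
        "x_g": sig.samples[:, 0],
        "y_g": sig.samples[:, 1],
        "z_g": sig.samples[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Gravity removal
# ---------------------------------------------------------------------------

def _highpass_sos(fs: float):
    return sps.butter(4, GRAVITY_CUTOFF_HZ, btype="highpass", fs=fs, output="sos")


def remove_gravity(sig: RawAccelSignal) -> np.ndarray:
    """Gravity-free dynamic acceleration, per axis, in g.

    Fourth-order Butterworth high-pass at 0.25 Hz applied forward-backward
    (zero phase), so a strictly constant input maps to an all-zero output and
    step-peak timing is unbiased.  Requires >= 10 s of signal.
    """
    if sig.duration_s < 10.0:
        raise ValueError("need >= 10 s of signal for gravity removal")
    sos = _highpass_sos(sig.sampling_rate)
    return sps.sosfiltfilt(sos, sig.samples, axis=0)


def _lowpass_vertical(sig: RawAccelSignal) -> np.ndarray:
    sos = sps.butter(4, GRAVITY_CUTOFF_HZ, btype="lowpass", fs=sig.sampling_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, sig.samples[:, 2])


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def epoch_signal(sig: RawAccelSignal, dynamic: np.ndarray,
                 epoch_length: float = 60.0) -> EpochSeries:
    """Summarize the dynamic signal into fixed epochs.

    A partial trailing epoch is dropped (with a warning), never padded, so
    per-minute statistics are not diluted.  ``counts`` is the rectified
    dynamic vector magnitude integrated over the epoch times
    :data:`COUNT_SCALE`.
    """
    fs = sig.sampling_rate
    samples_per_epoch = int(round(epoch_length * fs))
    if samples_per_epoch <= 0:
        raise ValueError("epoch_length too short for the sampling rate")
    n_epochs = sig.n_samples // samples_per_epoch
    if n_epochs == 0:
        raise ValueError("signal shorter than one epoch")
    if sig.n_samples % samples_per_epoch:
        warnings.warn("dropping partial trailing epoch", stacklevel=2)

    n_used = n_epochs * samples_per_epoch
    dyn = dynamic[:n_used].reshape(n_epochs, samples_per_epoch, 3)
    mag = np.linalg.norm(dyn, axis=2)

    mean_abs_vert = np.mean(np.abs(dyn[:, :, 2]), axis=1)
    dyn_rms_mg = np.sqrt(np.mean(mag ** 2, axis=1)) * 1000.0
    counts = mag.sum(axis=1) / fs * COUNT_SCALE

    starts = sig.start_time + pd.to_timedelta(
        np.arange(n_epochs) * epoch_length, unit="s")
    data = pd.DataFrame({
        "epoch_start": starts,
        "mean_abs_vertical_g": mean_abs_vert,
        "dyn_rms_mg": dyn_rms_mg,
        "counts": counts,
        "steps": 0,
        "standing_fraction": np.nan,
        "wear": True,
        "mets": np.nan,
    })
    return EpochSeries(start_time=sig.start_time, epoch_length=epoch_length,
                       data=data)


# ---------------------------------------------------------------------------
# Steps, posture, walking bouts
# ---------------------------------------------------------------------------

def detect_steps(sig: RawAccelSignal, dynamic: np.ndarray,
                 standing_mask: np.ndarray | None = None) -> list[StepEvent]:
    """Detect steps as vertical dynamic peaks >= 100 mg, 0.25 s apart.

    Deterministic; an empty result is valid.  ``standing_mask`` (per sample)
    sets each event's ``during_standing`` flag; without it steps are assumed
    standing.
    """
    fs = sig.sampling_rate
    vert = dynamic[:, 2]
    idx, props = sps.find_peaks(vert, height=STEP_PEAK_HEIGHT_G,
                                distance=max(1, int(round(STEP_REFRACTORY_S * fs))))
    events = []
    for i, h in zip(idx, props["peak_heights"]):
        standing = True if standing_mask is None else bool(standing_mask[i])
        events.append(StepEvent(
            time=sig.start_time + pd.Timedelta(seconds=i / fs),
            peak_accel_mg=float(h) * 1000.0,
            during_standing=standing,
        ))
    return events


def detect_posture(sig: RawAccelSignal) -> np.ndarray:
    """Per-sample standing mask from the low-pass vertical axis.

    Standing means the slowly varying vertical axis stays within a cone
    around +1 g, operationalized as low-pass z >= 0.7 g.
    """
    return _lowpass_vertical(sig) >= STANDING_VERTICAL_G


def standing_fraction_per_epoch(epochs: EpochSeries, standing_mask: np.ndarray,
                                sampling_rate: float) -> EpochSeries:
    """Fill ``standing_fraction`` from a per-sample standing mask."""
    spe = int(round(epochs.epoch_length * sampling_rate))
    n = len(epochs)
    frac = standing_mask[: n * spe].reshape(n, spe).mean(axis=1)
    epochs.data["standing_fraction"] = frac
    return epochs


def assign_steps_to_epochs(epochs: EpochSeries, steps: list[StepEvent]) -> EpochSeries:
    """Fill the per-epoch ``steps`` column (conserves the event count)."""
    counts = np.zeros(len(epochs), dtype=int)
    t0 = epochs.start_time
    for ev in steps:
        k = int((ev.time - t0).total_seconds() // epochs.epoch_length)
        if 0 <= k < len(epochs):
            counts[k] += 1
    epochs.data["steps"] = counts
    return epochs


def detect_walking_bouts(steps: list[StepEvent],
                         max_gap_s: float = CONSECUTIVE_STEP_GAP_S) -> list[WalkingBout]:
    """Group steps into walking bouts.

    A bout is a maximal run of steps with inter-step gaps <= ``max_gap_s``,
    every step during standing, and at least 3 steps.  Steps not during
    standing break (and are excluded from) runs.
    """
    events = sorted(steps, key=lambda e: e.time)
    bouts: list[WalkingBout] = []
    run: list[StepEvent] = []

    def flush(run):
        if len(run) >= MIN_BOUT_STEPS:
            bouts.append(WalkingBout(
                start=run[0].time, end=run[-1].time,
                step_times=tuple(ev.time for ev in run), n_steps=len(run)))

    for ev in events:
        if not ev.during_standing:
            flush(run)
            run = []
            continue
        if run and (ev.time - run[-1].time).total_seconds() > max_gap_s:
            flush(run)
            run = []
        run.append(ev)
    flush(run)
    return bouts
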