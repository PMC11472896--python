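import numpy as np
import pandas as pd
import pytest

from weartrial.signal_processing import EpochSeries, RawAccelSignal


def make_signal(samples, fs=100.0, start="2021-01-01 00:00:00"):
    return RawAccelSignal(start_time=pd.Timestamp(start), sampling_rate=fs,
                          samples=np.asarray(samples, float))


def upright_signal(duration_s, fs=100.0, vertical_extra=None,
                   start="2021-01-01 00:00:00"):
    """Upright wearer: gravity on z, optional added vertical dynamic trace."""
    n = int(round(duration_s * fs))
    acc = np.zeros((n, 3))
    acc[:, 2] = 1.0
    if vertical_extra is not None:
        acc[:, 2] += vertical_extra
    return make_signal(acc, fs=fs, start=start)


def make_epochs(n=1440, epoch_length=60.0, start="2021-01-01 00:00:00",
                **columns):
    """Epoch table built directly, bypassing raw-signal processing."""
    starts = pd.Timestamp(start) + pd.to_timedelta(
        np.arange(n) * epoch_length, unit="s")
    data = pd.DataFrame({
        "epoch_start": starts,
        "mean_abs_vertical_g": 0.0,
        "dyn_rms_mg": 0.0,
        "counts": 0.0,
        "steps": 0,
        "standing_fraction": 1.0,
        "wear": True,
        "mets": np.nan,
    })
    for k, v in columns.items():
        data[k] = v
    return EpochSeries(start_time=pd.Timestamp(start), epoch_length=epoch_length,
                       data=data)


@pytest.fixture(scope="session")
def small_trial():
    """One small raw-signal trial with missingness, processed end to end.

    Shared across end-to-end tests because simulating and processing whole
    24-h days dominates suite runtime.  10 Hz keeps the day tractable while
    leaving every detector's contract intact.
    """
    from weartrial.pipeline import daily_table
    from weartrial.synthetic import CohortConfig, inject_missingness, simulate_trial

    cfg = CohortConfig(n_patients=10, seed=31)
    ds = simulate_trial(cfg, n_days=4, sampling_rate=10.0,
                        delta_steps_week16=0.0, p_short_wear_day=0.2)
    ds = inject_missingness(ds, p_missing_period=0.15, seed=32)
    daily = daily_table(ds)
    return ds, daily
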