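"""End-to-end pipeline: raw day signals -> daily summaries -> effect table."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import activity_metrics as am
from . import signal_processing as sp
from . import trial_analysis as ta
from . import wear_validity as wv
from .synthetic import PERIODS, TrialDataset


@dataclass
class DayResult:
    """Everything derived from one patient-day of raw signal."""

    epochs: sp.EpochSeries
    steps: list
    bouts: list
    validity: wv.DayValidity
    summary: pd.Series       # the six outcomes


def process_day(sig: sp.RawAccelSignal, epoch_length: float = 60.0) -> DayResult:
    """Run one day through gravity removal, epoching, steps, posture,
    bouts, wear classification and the daily outcome summary."""
    dynamic = sp.remove_gravity(sig)
    epochs = sp.epoch_signal(sig, dynamic, epoch_length)
    standing = sp.detect_posture(sig)
    sp.standing_fraction_per_epoch(epochs, standing, sig.sampling_rate)
    steps = sp.detect_steps(sig, dynamic, standing_mask=standing)
    sp.assign_steps_to_epochs(epochs, steps)
    bouts = sp.detect_walking_bouts(steps)
    wv.detect_nonwear(epochs)
    am.estimate_mets(epochs)
    validity = wv.day_wear_hours(epochs)
    summary = am.summarize_day(epochs, len(steps), bouts, dynamic, sig)
    return DayResult(epochs=epochs, steps=steps, bouts=bouts,
                     validity=validity, summary=summary)


def daily_table(dataset: TrialDataset, epoch_length: float = 60.0) -> pd.DataFrame:
    """Daily-summary table for every signal in a simulated trial.

    Columns: ``patient_id, period, date, steps, lvpa_h, mvpa_h, vmu_cpm,
    mi_walk_mg, counts_k, wear_hours, valid``.
    """
    rows = []
    for (pid, period, day), sig in sorted(dataset.signals.items()):
        res = process_day(sig, epoch_length)
        row = {"patient_id": pid, "period": period,
               "date": str(res.validity.date)}
        row.update(res.summary.to_dict())
        row["wear_hours"] = res.validity.wear_hours_in_window
        row["valid"] = res.validity.valid
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_trial(daily: pd.DataFrame, covariates: pd.DataFrame, *,
                  timepoints=("week8", "week16"), per_trial: bool = False,
                  covariate_set=ta.DEFAULT_COVARIATES,
                  outcomes=am.OUTCOME_COLUMNS) -> list[ta.EffectEstimate]:
    """Daily summaries + covariates -> adjusted effect estimates.

    Runs the paired-cohort rule, change-from-baseline and the ANCOVA per
    outcome and timepoint; ``per_trial`` adds Reduced/Preserved estimates
    with the trial term dropped.
    """
    periods = ta.summarize_period(daily, outcomes=outcomes)
    cohort = ta.build_analysis_cohort(periods)
    effects = []
    for tp in timepoints:
        changes = ta.change_from_baseline(periods, cohort[tp], tp,
                                          outcomes=outcomes)
        changes = changes.dropna()
        subsets = [("pooled", changes)]
        if per_trial:
            for trial in ("Reduced", "Preserved"):
                pids = covariates.loc[covariates["trial"] == trial, "patient_id"]
                subsets.append((trial, changes[changes["patient_id"].isin(pids)]))
        for label, ch in subsets:
            for outcome in outcomes:
                effects.append(ta.ancova_effect(
                    ch, covariates, outcome, tp, cohort_label=label,
                    covariate_set=covariate_set))
    return effects
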