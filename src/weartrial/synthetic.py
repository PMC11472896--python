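"""Synthetic two-arm heart-failure trial generator with known ground truth.

No patient-level data from the accelerometer substudy are public, so every
downstream stage is exercised on simulated trials whose truth is recorded at
generation time.  Two levels of fidelity share one set of study conditions:

**Raw-signal path.**  Per patient and assessment period (baseline, week 8,
week 16) the generator renders whole 24-h days of triaxial acceleration:
gravity on the vertical axis while upright, band-limited Gaussian noise for
sedentary movement, discrete walking bouts as vertical sinusoids at the
patient's cadence with per-step amplitude jitter, and off-body (nonwear)
intervals as strictly constant signal.  True step counts, wear hours and
day validity are recorded exactly, by construction.

**Outcome-level path.**  For estimator calibration (type-I error, CI
coverage) the generator samples patient x period outcome summaries directly
from the additive Gaussian model the signal path targets — a between-patient
activity latent, secular period drift, an injected arm effect, and
period-summary noise.  The injected effect is the exact ground truth.

The treatment effect enters from week 8 onward as a multiplicative lift of
walking-bout rate and walk amplitude (signal path) or an additive shift
(outcome path), calibrated so the week-16 arm difference in expected daily
steps equals a configurable delta.  Missingness removes whole
patient-periods completely at random, matching a complete-case analysis.

Default cohort parameters reproduce the substudy's published baseline table:
mean age 71, 32 % female, mean LVEF 43 % (36 % of patients with LVEF <= 40 %
labelled the Reduced trial), NT-proBNP log-normal with median 861 and IQR
514-1591 pg/mL, 84 % NYHA class II.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .signal_processing import RawAccelSignal, write_signal

__all__ = [
    "CohortConfig",
    "ActivityProfile",
    "TrialDataset",
    "OutcomeModel",
    "OutcomeDataset",
    "simulate_cohort",
    "simulate_day_signal",
    "simulate_trial",
    "inject_missingness",
    "simulate_outcome_dataset",
    "default_covariate_params",
    "PERIODS",
    "OUTCOMES",
]

PERIODS = ("baseline", "week8", "week16")
OUTCOMES = ("steps", "lvpa_h", "mvpa_h", "vmu_cpm", "mi_walk_mg", "counts_k")

ARM_TREAT = "dapagliflozin"
ARM_PLACEBO = "placebo"


def default_covariate_params() -> dict:
    """Baseline-table defaults for the covariate simulator."""
    return {
        "age_mean": 71.0, "age_sd": 9.0,
        "frac_female": 0.32,
        "lvef_reduced_mean": 33.0, "lvef_reduced_sd": 5.0,
        "lvef_preserved_mean": 49.0, "lvef_preserved_sd": 7.0,
        "ntprobnp_log_mu": float(np.log(861.0)), "ntprobnp_log_sigma": 0.84,
        "nyha_probs": {"I": 0.08, "II": 0.84, "III": 0.08},
        "region_probs": {"Europe": 0.40, "NorthAmerica": 0.25,
                         "SouthAmerica": 0.20, "Asia": 0.15},
        "bmi_mean": 29.0, "bmi_sd": 5.0,
    }


@dataclass
class CohortConfig:
    """Study conditions of a simulated two-arm trial cohort."""

    n_patients: int = 211
    allocation_ratio: float = 107 / 211
    frac_reduced_trial: float = 75 / 211
    covariate_params: dict = field(default_factory=default_covariate_params)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        for name in ("allocation_ratio", "frac_reduced_trial"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for key in ("nyha_probs", "region_probs"):
            p = self.covariate_params[key]
            if abs(sum(p.values()) - 1.0) > 1e-9:
                raise ValueError(f"{key} must sum to 1")


@dataclass
class ActivityProfile:
    """Per-patient daily activity pattern rendered by the signal generator.

    Accelerations are in mg, times of day in hours, bout durations in
    seconds, cadence in steps/second.  ``period_effect`` multiplies the
    walking-bout rate and walk amplitude per assessment period (secular
    drift plus any injected arm effect).
    """

    sedentary_mean_dynamic_accel: float = 6.0
    daily_walk_bouts: float = 40.0
    bout_duration: float = 60.0
    cadence: float = 1.8
    walk_peak_accel: float = 300.0
    wear_start: float = 6.5
    wear_end: float = 21.5
    nonwear_blocks: tuple = ()
    period_effect: dict = field(default_factory=lambda: {p: 1.0 for p in PERIODS})

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.walk_peak_accel <= self.sedentary_mean_dynamic_accel:
            raise ValueError("walk_peak_accel must exceed sedentary level")
        if not self.wear_start < self.wear_end:
            raise ValueError("wear_start must precede wear_end")
        blocks = sorted(self.nonwear_blocks)
        for (s1, d1), (s2, _) in zip(blocks, blocks[1:]):
            if s1 + d1 > s2:
                raise ValueError("nonwear blocks overlap")

    @property
    def expected_daily_steps(self) -> float:
        return self.daily_walk_bouts * round(self.bout_duration * self.cadence)


@dataclass
class TrialDataset:
    """Covariates, raw signals keyed (patient, period, day), and truth.

    ``ground_truth`` maps patient ids to per-period records (day-level true
    steps, wear hours, validity; expected daily steps) plus the injected
    week-16 arm effect per outcome and the set of analysis-eligible
    patients.
    """

    covariates: pd.DataFrame
    signals: dict
    ground_truth: dict

    def write(self, outdir) -> None:
        """Write covariate CSV, per-day signal CSVs and ground-truth JSON."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        for (pid, period, day), sig in self.signals.items():
            write_signal(sig, out / f"{pid}_{period}_{day}.csv")
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortConfig) -> TrialDataset:
    """Draw the covariate table; signals stay empty.

    Arm counts follow the allocation ratio deterministically (rounded), so
    211 patients at the trial's 107:104 ratio reproduce those exact counts;
    the trial label is consistent with LVEF (Reduced <-> LVEF <= 40 %).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    p = config.covariate_params

    n_treat = int(round(n * config.allocation_ratio))
    arm = np.array([ARM_TREAT] * n_treat + [ARM_PLACEBO] * (n - n_treat))
    rng.shuffle(arm)

    n_reduced = int(round(n * config.frac_reduced_trial))
    trial = np.array(["Reduced"] * n_reduced + ["Preserved"] * (n - n_reduced))
    rng.shuffle(trial)

    lvef = np.where(
        trial == "Reduced",
        np.clip(rng.normal(p["lvef_reduced_mean"], p["lvef_reduced_sd"], n), 15, 40),
        np.clip(rng.normal(p["lvef_preserved_mean"], p["lvef_preserved_sd"], n), 41, 70),
    )
    nyha_levels = list(p["nyha_probs"])
    region_levels = list(p["region_probs"])
    cov = pd.DataFrame({
        "patient_id": [f"P{i:04d}" for i in range(n)],
        "trial": trial,
        "arm": arm,
        "age": np.clip(rng.normal(p["age_mean"], p["age_sd"], n), 40, 95),
        "sex": np.where(rng.random(n) < p["frac_female"], "F", "M"),
        "bmi": np.clip(rng.normal(p["bmi_mean"], p["bmi_sd"], n), 16, 50),
        "lvef": lvef,
        "ntprobnp": rng.lognormal(p["ntprobnp_log_mu"], p["ntprobnp_log_sigma"], n),
        "nyha": rng.choice(nyha_levels, n, p=[p["nyha_probs"][k] for k in nyha_levels]),
        "region": rng.choice(region_levels, n,
                             p=[p["region_probs"][k] for k in region_levels]),
    })
    return TrialDataset(covariates=cov, signals={}, ground_truth={"patients": {}})


# ---------------------------------------------------------------------------
# Raw-signal generation
# ---------------------------------------------------------------------------

def _band_limited_noise(rng, n, fs, sigma):
    """Gaussian movement noise band-limited below ~2 Hz (gentle fidgeting)."""
    white = rng.standard_normal(n)
    if fs > 5:
        sos = sps.butter(2, 2.0, btype="lowpass", fs=fs, output="sos")
        white = sps.sosfilt(sos, white)
        white /= max(np.std(white), 1e-12)
    return white * sigma


def simulate_day_signal(profile: ActivityProfile, seed: int,
                        sampling_rate: float = 100.0, period: str = "baseline",
                        start_time="2021-01-01 00:00:00",
                        ) -> tuple[RawAccelSignal, dict]:
    """Render one 24-h day of triaxial acceleration for one patient.

    Returns the signal and a ground-truth record holding the exact number of
    generated step events, the realized bout count, and wear hours inside the
    06:00-22:00 protocol window.  Walking bouts are vertical sinusoids at the
    configured cadence (one positive peak per step) with ±20 % per-step
    amplitude jitter plus half-amplitude horizontal sway; off-body intervals
    are strictly constant.
    """
    rng = np.random.default_rng(seed)
    fs = sampling_rate
    n = int(round(86400 * fs))
    t = np.arange(n) / fs

    effect = profile.period_effect.get(period, 1.0)

    # worn, upright: gravity on z plus sedentary movement noise
    sigma_g = profile.sedentary_mean_dynamic_accel / 1000.0 / np.sqrt(2 / np.pi)
    acc = np.empty((n, 3))
    for ax in range(3):
        acc[:, ax] = _band_limited_noise(rng, n, fs, sigma_g)
    acc[:, 2] += 1.0

    # walking bouts inside the wear interval, clear of nonwear blocks
    lam = profile.daily_walk_bouts * effect
    n_bouts = int(rng.poisson(lam))
    amp_g = profile.walk_peak_accel / 1000.0 * np.sqrt(effect)
    steps_per_bout = max(1, int(round(profile.bout_duration * profile.cadence)))
    bout_dur = steps_per_bout / profile.cadence

    blocked = [(s, s + d) for s, d in profile.nonwear_blocks]
    day_hours = (profile.wear_start, profile.wear_end)
    placed: list[float] = []
    true_steps = 0
    attempts = 0
    b = 0
    while b < n_bouts and attempts < 50 * max(n_bouts, 1):
        attempts += 1
        start_h = rng.uniform(day_hours[0], day_hours[1] - bout_dur / 3600.0)
        end_h = start_h + bout_dur / 3600.0
        if any(s < end_h and start_h < e for s, e in blocked):
            continue
        if any(abs(start_h - p0) * 3600.0 < bout_dur + 5.0 for p0 in placed):
            continue
        i0 = int(start_h * 3600 * fs)
        i1 = min(i0 + int(round(bout_dur * fs)), n)
        tt = t[i0:i1] - t[i0]
        phase = 2 * np.pi * profile.cadence * tt
        cyc = np.minimum((phase // (2 * np.pi)).astype(int), steps_per_bout - 1)
        jit = rng.uniform(0.8, 1.2, steps_per_bout)
        acc[i0:i1, 2] += amp_g * jit[cyc] * np.sin(phase)
        acc[i0:i1, 0] += 0.5 * amp_g * np.sin(phase / 2)
        acc[i0:i1, 1] += 0.3 * amp_g * np.cos(phase)
        placed.append(start_h)
        true_steps += steps_per_bout
        b += 1

    # off-body: strictly constant, device lying flat (x reads gravity)
    offbody = [(0.0, profile.wear_start), (profile.wear_end, 24.0)]
    offbody += [(s, s + d) for s, d in profile.nonwear_blocks]
    for s_h, e_h in offbody:
        i0, i1 = int(s_h * 3600 * fs), int(e_h * 3600 * fs)
        if i1 > i0:
            acc[i0:i1] = (1.0, 0.0, 0.0)

    # exact wear hours inside the 06:00-22:00 protocol window
    def overlap(a0, a1, b0, b1):
        return max(0.0, min(a1, b1) - max(a0, b0))

    wear_h = overlap(profile.wear_start, profile.wear_end, 6.0, 22.0)
    wear_h -= sum(overlap(s, e, max(6.0, profile.wear_start),
                          min(22.0, profile.wear_end)) for s, e in
                  ((s, s + d) for s, d in profile.nonwear_blocks))

    sig = RawAccelSignal(start_time=pd.Timestamp(start_time), sampling_rate=fs,
                         samples=acc)
    truth = {
        "true_steps": int(true_steps),
        "n_bouts": int(b),
        "expected_steps": float(lam * steps_per_bout),
        "wear_hours_in_window": float(wear_h),
        "valid": bool(wear_h >= 10.0),
    }
    return sig, truth


def simulate_trial(config: CohortConfig, *, n_days: int = 7,
                   sampling_rate: float = 100.0,
                   delta_steps_week16: float = 0.0,
                   secular_drift: dict | None = None,
                   p_short_wear_day: float = 0.1,
                   base_profile: ActivityProfile | None = None,
                   between_patient_sd: float = 0.25) -> TrialDataset:
    """Full raw-signal trial: covariates + signals + exact ground truth.

    Walking-bout rates vary log-normally between patients.  Treated patients
    get a multiplicative lift on bout rate and walk amplitude from week 8
    onward, sized against their own expected steps so the week-16 arm
    difference in expected daily steps equals ``delta_steps_week16``.
    Occasional short-wear days (worn ~09:00-13:30) are invalid by
    construction and recorded as such.
    """
    drift = secular_drift or {"baseline": 1.0, "week8": 0.92, "week16": 0.82}
    base = base_profile or ActivityProfile()
    ds = simulate_cohort(config)
    rng = np.random.default_rng(config.seed + 1)
    truth_patients: dict = {}

    for _, row in ds.covariates.iterrows():
        pid = row["patient_id"]
        scale = float(np.exp(rng.normal(0.0, between_patient_sd)))
        steps_per_bout = max(1, int(round(base.bout_duration * base.cadence)))
        exp_base_steps = base.daily_walk_bouts * scale * steps_per_bout
        lift = 1.0
        if row["arm"] == ARM_TREAT and delta_steps_week16 != 0.0:
            lift = 1.0 + delta_steps_week16 / (exp_base_steps * drift["week16"])
        period_effect = {
            p: drift[p] * (lift if p in ("week8", "week16") else 1.0)
            for p in PERIODS
        }
        profile = replace(base,
                          daily_walk_bouts=base.daily_walk_bouts * scale,
                          period_effect=period_effect)
        rec = {"expected_daily_steps":
               {p: exp_base_steps * period_effect[p] for p in PERIODS},
               "periods": {}}
        for period in PERIODS:
            days = []
            for day in range(n_days):
                day_prof = profile
                if rng.random() < p_short_wear_day:
                    day_prof = replace(profile, wear_start=9.0, wear_end=13.5,
                                       daily_walk_bouts=profile.daily_walk_bouts / 4)
                seed_day = int(rng.integers(0, 2**31 - 1))
                sig, dtruth = simulate_day_signal(
                    day_prof, seed_day, sampling_rate=sampling_rate,
                    period=period,
                    start_time=pd.Timestamp("2021-01-01") + pd.Timedelta(days=day))
                ds.signals[(pid, period, day)] = sig
                days.append(dtruth)
            rec["periods"][period] = {
                "present": True,
                "days": days,
                "n_valid_days": sum(d["valid"] for d in days),
                "eligible": sum(d["valid"] for d in days) >= 3,
            }
        truth_patients[pid] = rec

    ds.ground_truth = {
        "patients": truth_patients,
        "delta_week16": {"steps": float(delta_steps_week16)},
        "analysis_eligible": _eligible_patients(truth_patients),
    }
    return ds


def _eligible_patients(truth_patients: dict) -> list[str]:
    out = []
    for pid, rec in truth_patients.items():
        pb = rec["periods"].get("baseline")
        pw = rec["periods"].get("week16")
        if (pb and pb["present"] and pb["eligible"]
                and pw and pw["present"] and pw["eligible"]):
            out.append(pid)
    return sorted(out)


def inject_missingness(dataset: TrialDataset, p_missing_period: float,
                       seed: int) -> TrialDataset:
    """Remove whole (patient, period) signal sets completely at random.

    Ground truth is updated so the recorded analysis-eligible set reflects
    the remaining data.
    """
    if not 0.0 <= p_missing_period <= 1.0:
        raise ValueError("p_missing_period must lie in [0, 1]")
    if not dataset.signals:
        raise ValueError("dataset has no signals to drop")
    rng = np.random.default_rng(seed)
    truth = dataset.ground_truth
    signals = dict(dataset.signals)
    for pid in dataset.covariates["patient_id"]:
        for period in PERIODS:
            if rng.random() < p_missing_period:
                for day in range(100):
                    signals.pop((pid, period, day), None)
                rec = truth["patients"].get(pid)
                if rec and period in rec["periods"]:
                    rec["periods"][period]["present"] = False
                    rec["periods"][period]["eligible"] = False
    truth["analysis_eligible"] = _eligible_patients(truth["patients"])
    return TrialDataset(covariates=dataset.covariates, signals=signals,
                        ground_truth=truth)


# ---------------------------------------------------------------------------
# Outcome-level fast path
# ---------------------------------------------------------------------------

@dataclass
class OutcomeModel:
    """Additive Gaussian model for patient x period outcome summaries.

    Per outcome: mean level, between-patient SD (loading on one shared
    activity latent), period-summary residual SD, and secular drift at week
    8 / week 16.  Defaults put the steps change SD near 2000/day and the VMU
    change SD near 90 cpm, the scale seen in heart-failure actigraphy.
    """

    mean: dict = field(default_factory=lambda: {
        "steps": 4500.0, "lvpa_h": 4.0, "mvpa_h": 0.7, "vmu_cpm": 250.0,
        "mi_walk_mg": 230.0, "counts_k": 400.0})
    between_sd: dict = field(default_factory=lambda: {
        "steps": 1800.0, "lvpa_h": 1.5, "mvpa_h": 0.5, "vmu_cpm": 80.0,
        "mi_walk_mg": 50.0, "counts_k": 150.0})
    resid_sd: dict = field(default_factory=lambda: {
        "steps": 1400.0, "lvpa_h": 0.8, "mvpa_h": 0.35, "vmu_cpm": 65.0,
        "mi_walk_mg": 25.0, "counts_k": 70.0})
    drift_week8: dict = field(default_factory=lambda: {
        "steps": -400.0, "lvpa_h": -0.15, "mvpa_h": -0.08, "vmu_cpm": -10.0,
        "mi_walk_mg": -2.0, "counts_k": -15.0})
    drift_week16: dict = field(default_factory=lambda: {
        "steps": -850.0, "lvpa_h": -0.30, "mvpa_h": -0.17, "vmu_cpm": -25.0,
        "mi_walk_mg": -5.0, "counts_k": -30.0})
    age_slope: dict = field(default_factory=lambda: {
        "steps": -40.0, "lvpa_h": -0.03, "mvpa_h": -0.01, "vmu_cpm": -1.5,
        "mi_walk_mg": -0.8, "counts_k": -3.0})


@dataclass
class OutcomeDataset:
    """Covariates + wide patient x period outcome table + injected truth."""

    covariates: pd.DataFrame
    periods: pd.DataFrame          # patient_id, period, six outcome columns
    true_delta: dict               # outcome -> injected week-16 arm effect


def simulate_outcome_dataset(config: CohortConfig, *,
                             model: OutcomeModel | None = None,
                             delta: dict | float = 0.0,
                             delta_week8_fraction: float = 0.5,
                             delta_by_trial: dict | None = None,
                             p_missing_week8: float = 0.15,
                             p_missing_week16: float = 0.0,
                             n_valid_days: int = 7) -> OutcomeDataset:
    """Sample period summaries directly from the outcome-level model.

    ``delta`` is the injected week-16 arm effect, either one number applied
    to steps only or a per-outcome dict; week 8 receives
    ``delta_week8_fraction`` of it.  ``delta_by_trial`` optionally overrides
    the steps effect per trial (heterogeneity scenarios for the interaction
    test).  Residual SD scales with 1/sqrt(n_valid_days/7) to mimic
    averaging over valid days.  Missing periods are removed completely at
    random; under ``delta = 0`` the ground-truth arm effect is exactly zero.
    """
    model = model or OutcomeModel()
    if isinstance(delta, (int, float)):
        delta = {"steps": float(delta)}
    full_delta = {k: float(delta.get(k, 0.0)) for k in OUTCOMES}

    ds = simulate_cohort(config)
    cov = ds.covariates
    n = len(cov)
    rng = np.random.default_rng(config.seed + 10_000)
    latent = rng.standard_normal(n)
    age_c = cov["age"].to_numpy() - 71.0
    treat = (cov["arm"] == ARM_TREAT).to_numpy(float)
    resid_scale = np.sqrt(7.0 / max(n_valid_days, 1))

    frames = []
    for period in PERIODS:
        row = {"patient_id": cov["patient_id"], "period": period}
        for k in OUTCOMES:
            drift = {"baseline": 0.0, "week8": model.drift_week8[k],
                     "week16": model.drift_week16[k]}[period]
            eff = full_delta[k]
            if k == "steps" and delta_by_trial is not None:
                eff = cov["trial"].map(delta_by_trial).to_numpy(float)
            arm_shift = {"baseline": 0.0,
                         "week8": delta_week8_fraction,
                         "week16": 1.0}[period] * eff * treat
            row[k] = (model.mean[k] + model.age_slope[k] * age_c
                      + model.between_sd[k] * latent + drift + arm_shift
                      + rng.normal(0.0, model.resid_sd[k] * resid_scale, n))
        frames.append(pd.DataFrame(row))
    periods = pd.concat(frames, ignore_index=True)
    periods["n_valid_days"] = n_valid_days

    miss8 = rng.random(n) < p_missing_week8
    miss16 = rng.random(n) < p_missing_week16
    pid_idx = periods["patient_id"].map(
        {p: i for i, p in enumerate(cov["patient_id"])}).to_numpy()
    drop = (((periods["period"] == "week8").to_numpy() & miss8[pid_idx])
            | ((periods["period"] == "week16").to_numpy() & miss16[pid_idx]))
    periods = periods.loc[~drop].reset_index(drop=True)

    return OutcomeDataset(covariates=cov, periods=periods, true_delta=full_delta)
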