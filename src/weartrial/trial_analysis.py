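"""Change-from-baseline ANCOVA treatment effects on activity outcomes.

Valid days are averaged into one summary per patient x assessment period;
the analysis cohort is the complete-case, paired set of patients with
eligible data at both baseline and week 16 (week-8 analyses use the subset
of that cohort with week-8 data; no imputation anywhere).  For each outcome
the adjusted between-group difference is the treatment-arm coefficient of an
ordinary-least-squares ANCOVA of the change on arm plus baseline value of
the outcome, LVEF, trial, age, sex, BMI, log NT-proBNP, NYHA class and
geographic region, with a t-based 95 % CI on residual degrees of freedom.
Pooled and per-trial estimates are supported, plus a Wald test of the
arm x trial interaction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .synthetic import OUTCOMES, ARM_TREAT, PERIODS

__all__ = [
    "EffectEstimate",
    "summarize_period",
    "build_analysis_cohort",
    "change_from_baseline",
    "ancova_effect",
    "interaction_test",
    "report",
    "effects_to_json",
    "effects_from_json",
    "DEFAULT_COVARIATES",
]

#: Adjustment set of the primary analysis, beyond the treatment arm.
DEFAULT_COVARIATES = ("baseline", "lvef", "trial", "age", "sex", "bmi",
                      "log_ntprobnp", "nyha", "region")

ROUND_DECIMALS = {"steps": 0, "lvpa_h": 2, "mvpa_h": 2, "vmu_cpm": 0,
                  "mi_walk_mg": 2, "counts_k": 0}


@dataclass
class EffectEstimate:
    """Adjusted between-group difference for one outcome x timepoint."""

    outcome: str
    timepoint: str
    cohort: str                 # pooled / Reduced / Preserved
    n_treat: int
    n_placebo: int
    mean_change_treat: float
    sd_change_treat: float
    mean_change_placebo: float
    sd_change_placebo: float
    difference: float
    se: float
    ci_lower: float
    ci_upper: float
    p_value: float


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def summarize_period(daily: pd.DataFrame, *, min_valid_days: int = 3,
                     outcomes=OUTCOMES) -> pd.DataFrame:
    """Average valid days into one row per patient x period.

    ``daily`` needs columns ``patient_id, period, valid`` plus the outcome
    columns.  Periods with fewer than ``min_valid_days`` valid days are
    dropped (ineligible).  Walking intensity, missing on zero-bout days,
    is averaged over the valid days where it exists.
    """
    valid = daily.loc[daily["valid"].astype(bool)]
    rows = []
    for (pid, period), grp in valid.groupby(["patient_id", "period"], sort=True):
        if len(grp) < min_valid_days:
            continue
        row = {"patient_id": pid, "period": period, "n_valid_days": len(grp)}
        for k in outcomes:
            row[k] = float(grp[k].mean(skipna=True))
        rows.append(row)
    cols = ["patient_id", "period", "n_valid_days", *outcomes]
    return pd.DataFrame(rows, columns=cols)


def build_analysis_cohort(periods: pd.DataFrame) -> dict:
    """Paired-data cohort: patients with baseline and week-16 summaries.

    Returns ``{"week16": [...], "week8": [...]}`` where the week-8 list is
    the subset of the week-16 cohort that also has week-8 data.  An empty
    week-16 cohort is an analysis error.
    """
    have = {p: set(periods.loc[periods["period"] == p, "patient_id"])
            for p in PERIODS}
    cohort16 = sorted(have["baseline"] & have["week16"])
    if not cohort16:
        raise ValueError("analysis cohort is empty: no patient has paired "
                         "baseline and week-16 data")
    cohort8 = sorted(set(cohort16) & have["week8"])
    return {"week16": cohort16, "week8": cohort8}


def change_from_baseline(periods: pd.DataFrame, cohort: list[str],
                         timepoint: str, outcomes=OUTCOMES) -> pd.DataFrame:
    """Follow-up minus baseline per outcome, for the given cohort.

    Output columns: ``patient_id``, ``change_<outcome>`` and
    ``baseline_<outcome>``; one row per patient with both periods present.
    """
    base = periods.loc[(periods["period"] == "baseline")
                       & periods["patient_id"].isin(cohort)]
    fup = periods.loc[(periods["period"] == timepoint)
                      & periods["patient_id"].isin(cohort)]
    merged = base.merge(fup, on="patient_id", suffixes=("_b", "_f"))
    out = pd.DataFrame({"patient_id": merged["patient_id"]})
    for k in outcomes:
        out[f"change_{k}"] = merged[f"{k}_f"] - merged[f"{k}_b"]
        out[f"baseline_{k}"] = merged[f"{k}_b"]
    return out


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------

def _dummies(series: pd.Series, name: str) -> pd.DataFrame:
    """Dummy-code against the most frequent level (the reference)."""
    ref = series.value_counts().idxmax()
    levels = [lv for lv in series.unique() if lv != ref]
    return pd.DataFrame({f"{name}[{lv}]": (series == lv).astype(float)
                         for lv in sorted(map(str, levels))})


def build_design(changes: pd.DataFrame, covariates: pd.DataFrame, outcome: str,
                 covariate_set=DEFAULT_COVARIATES,
                 interaction: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and response for the ANCOVA of one outcome's change."""
    df = changes.merge(covariates, on="patient_id", validate="one_to_one")
    y = df[f"change_{outcome}"]
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["arm"] = (df["arm"] == ARM_TREAT).astype(float)

    single_trial = df["trial"].nunique() < 2
    for cv in covariate_set:
        if cv == "baseline":
            X[f"baseline_{outcome}"] = df[f"baseline_{outcome}"]
        elif cv == "trial":
            if not single_trial:
                X["trial[Reduced]"] = (df["trial"] == "Reduced").astype(float)
        elif cv == "log_ntprobnp":
            X["log_ntprobnp"] = np.log(df["ntprobnp"])
        elif cv == "sex":
            X["sex[F]"] = (df["sex"] == "F").astype(float)
        elif cv in ("nyha", "region"):
            X = pd.concat([X, _dummies(df[cv].astype(str), cv)], axis=1)
        else:
            X[cv] = df[cv].astype(float)
    if interaction:
        if single_trial:
            raise ValueError("interaction test needs both trials represented")
        X["arm:trial[Reduced]"] = X["arm"] * X["trial[Reduced]"]

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(X.shape[1])
               if abs(r[j, j]) < 1e-8 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, y


def ancova_effect(changes: pd.DataFrame, covariates: pd.DataFrame, outcome: str,
                  timepoint: str, cohort_label: str = "pooled",
                  covariate_set=DEFAULT_COVARIATES) -> EffectEstimate:
    """Adjusted between-group difference with t-based 95 % CI.

    The effect is the arm coefficient of the OLS fit of the change on arm
    plus the adjustment set (trial omitted automatically in single-trial
    cohorts); raw per-arm mean change and SD are reported alongside.
    """
    df = changes.merge(covariates, on="patient_id", validate="one_to_one")
    arm_counts = df["arm"].value_counts()
    if arm_counts.min() < 2 or len(arm_counts) < 2:
        raise ValueError("need at least 2 patients per arm")

    X, y = build_design(changes, covariates, outcome, covariate_set)
    fit = sm.OLS(y, X).fit()
    beta = float(fit.params["arm"])
    se = float(fit.bse["arm"])
    tq = stats.t.ppf(0.975, fit.df_resid)

    ch = df[f"change_{outcome}"]
    treat = df["arm"] == ARM_TREAT
    return EffectEstimate(
        outcome=outcome, timepoint=timepoint, cohort=cohort_label,
        n_treat=int(treat.sum()), n_placebo=int((~treat).sum()),
        mean_change_treat=float(ch[treat].mean()),
        sd_change_treat=float(ch[treat].std(ddof=1)),
        mean_change_placebo=float(ch[~treat].mean()),
        sd_change_placebo=float(ch[~treat].std(ddof=1)),
        difference=beta, se=se,
        ci_lower=beta - tq * se, ci_upper=beta + tq * se,
        p_value=float(fit.pvalues["arm"]),
    )


def interaction_test(changes: pd.DataFrame, covariates: pd.DataFrame,
                     outcome: str, covariate_set=DEFAULT_COVARIATES) -> float:
    """Wald t-test p-value for treatment-effect heterogeneity across trials.

    Adds an arm x trial term to the pooled ANCOVA and returns its p-value.
    """
    X, y = build_design(changes, covariates, outcome, covariate_set,
                        interaction=True)
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues["arm:trial[Reduced]"])


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report(effects: list[EffectEstimate]) -> pd.DataFrame:
    """One formatted row per outcome x timepoint x cohort.

    Differences and CI bounds are rounded to the display precision customary
    for each outcome (integers for steps, VMU and counts; two decimals for
    hours and mg); full precision lives in the JSON export.
    """
    cols = ["outcome", "timepoint", "cohort", "n_treat", "n_placebo",
            "mean_change_treat", "sd_change_treat", "mean_change_placebo",
            "sd_change_placebo", "difference", "ci_95"]
    rows = []
    for e in effects:
        d = ROUND_DECIMALS.get(e.outcome, 2)
        fmt = (lambda v, d=d: round(float(v), d) if d else int(round(float(v))))
        rows.append({
            "outcome": e.outcome, "timepoint": e.timepoint, "cohort": e.cohort,
            "n_treat": e.n_treat, "n_placebo": e.n_placebo,
            "mean_change_treat": fmt(e.mean_change_treat),
            "sd_change_treat": fmt(e.sd_change_treat),
            "mean_change_placebo": fmt(e.mean_change_placebo),
            "sd_change_placebo": fmt(e.sd_change_placebo),
            "difference": fmt(e.difference),
            "ci_95": f"({fmt(e.ci_lower)}–{fmt(e.ci_upper)})",
        })
    return pd.DataFrame(rows, columns=cols)


def effects_to_json(effects: list[EffectEstimate], path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(e) for e in effects], fh, indent=1)


def effects_from_json(path) -> list[EffectEstimate]:
    with open(path) as fh:
        return [EffectEstimate(**rec) for rec in json.load(fh)]
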