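"""Monte-Carlo calibration of the ANCOVA estimator on the outcome generator.

These routines re-run the whole estimation chain (simulate -> paired cohort
-> change from baseline -> adjusted ANCOVA) over many replicate trials to
measure type-I error, CI coverage, bias and interaction-test uniformity —
the quantities that make a change-from-baseline analysis trustworthy when
the real patient-level data cannot be shared.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import trial_analysis as ta
from .synthetic import CohortConfig, simulate_outcome_dataset

__all__ = ["replicate_effects", "type_i_error", "effect_recovery"]


def replicate_effects(n_reps: int, n_patients: int, seed: int, *,
                      delta: float = 0.0, outcome: str = "steps",
                      with_interaction: bool = False,
                      p_missing_week8: float = 0.15) -> dict:
    """Fit the week-16 ANCOVA on ``n_reps`` independent simulated trials.

    Returns arrays of point estimates, CI bounds, and (optionally) the
    arm x trial interaction p-values, plus the injected truth.
    """
    est = np.empty(n_reps)
    lo = np.empty(n_reps)
    hi = np.empty(n_reps)
    ip = np.empty(n_reps) if with_interaction else None
    for r in range(n_reps):
        cfg = CohortConfig(n_patients=n_patients, seed=seed + r)
        ds = simulate_outcome_dataset(cfg, delta=delta,
                                      p_missing_week8=p_missing_week8)
        cohort = ta.build_analysis_cohort(ds.periods)
        ch = ta.change_from_baseline(ds.periods, cohort["week16"], "week16",
                                     outcomes=(outcome,))
        eff = ta.ancova_effect(ch, ds.covariates, outcome, "week16")
        est[r], lo[r], hi[r] = eff.difference, eff.ci_lower, eff.ci_upper
        if with_interaction:
            ip[r] = ta.interaction_test(ch, ds.covariates, outcome)
    return {"estimates": est, "ci_lower": lo, "ci_upper": hi,
            "interaction_p": ip, "true_delta": float(delta)}


def type_i_error(n_reps: int = 2000, n_patients: int = 200,
                 seed: int = 0) -> dict:
    """Null-generator calibration: how often the 95 % CI excludes zero,
    and whether the interaction p-value is uniform (KS test)."""
    rep = replicate_effects(n_reps, n_patients, seed, delta=0.0,
                            with_interaction=True)
    excl = float(np.mean((rep["ci_lower"] > 0) | (rep["ci_upper"] < 0)))
    ks = stats.kstest(rep["interaction_p"], "uniform")
    return {"exclusion_rate": excl, "interaction_ks_p": float(ks.pvalue),
            "n_reps": n_reps, "n_patients": n_patients}


def effect_recovery(delta: float = 800.0, n_reps: int = 500,
                    n_patients: int = 1000, seed: int = 0) -> dict:
    """Bias and CI coverage when a known week-16 step effect is injected."""
    rep = replicate_effects(n_reps, n_patients, seed, delta=delta)
    est = rep["estimates"]
    cover = float(np.mean((rep["ci_lower"] <= delta)
                          & (delta <= rep["ci_upper"])))
    return {"mean_estimate": float(est.mean()),
            "sem": float(est.std(ddof=1) / np.sqrt(n_reps)),
            "coverage": cover, "true_delta": float(delta),
            "n_reps": n_reps, "n_patients": n_patients}
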