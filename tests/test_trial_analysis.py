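"""Period aggregation, paired cohort, ANCOVA vs normal-equations oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from weartrial import synthetic as syn
from weartrial import trial_analysis as ta


def _daily(rows):
    cols = ["patient_id", "period", "valid", *syn.OUTCOMES]
    out = []
    for pid, period, valid, steps in rows:
        out.append(dict(patient_id=pid, period=period, valid=valid, steps=steps,
                        lvpa_h=1.0, mvpa_h=0.5, vmu_cpm=100.0,
                        mi_walk_mg=np.nan, counts_k=10.0))
    return pd.DataFrame(out, columns=cols)


class TestSummarizePeriod:
    def test_mean_over_valid_days(self):
        daily = _daily([("P1", "baseline", True, v) for v in (1000, 2000, 3000)])
        out = ta.summarize_period(daily)
        assert out.loc[0, "steps"] == 2000.0
        assert out.loc[0, "n_valid_days"] == 3

    def test_missing_aware_mean_for_walk_intensity(self):
        daily = _daily([("P1", "baseline", True, 1000)] * 3)
        daily.loc[0, "mi_walk_mg"] = 40.0
        daily.loc[1, "mi_walk_mg"] = 60.0
        out = ta.summarize_period(daily)
        assert out.loc[0, "mi_walk_mg"] == 50.0

    def test_ineligible_period_absent(self):
        daily = _daily([("P1", "baseline", True, 1000),
                        ("P1", "baseline", True, 1500),
                        ("P1", "baseline", False, 9000)])
        assert len(ta.summarize_period(daily)) == 0


class TestAnalysisCohort:
    def test_paired_data_rule(self):
        periods = pd.DataFrame({
            "patient_id": ["A", "A", "A", "B", "B", "C", "C"],
            "period": ["baseline", "week8", "week16",
                       "baseline", "week16", "baseline", "week8"],
        })
        cohort = ta.build_analysis_cohort(periods)
        assert cohort["week16"] == ["A", "B"]   # C lacks week 16
        assert cohort["week8"] == ["A"]          # B lacks week 8

    def test_empty_cohort_is_an_error(self):
        periods = pd.DataFrame({"patient_id": ["A"], "period": ["baseline"]})
        with pytest.raises(ValueError, match="empty"):
            ta.build_analysis_cohort(periods)


class TestChangeFromBaseline:
    def _periods(self):
        return pd.DataFrame({
            "patient_id": ["A", "A", "B", "B"],
            "period": ["baseline", "week16"] * 2,
            **{k: [5000.0, 5800.0, 4000.0, 4000.0] if k == "steps"
               else [1.0, 1.0, 1.0, 1.0] for k in syn.OUTCOMES},
        })

    def test_subtraction(self):
        ch = ta.change_from_baseline(self._periods(), ["A", "B"], "week16")
        assert ch.set_index("patient_id").loc["A", "change_steps"] == 800.0
        assert ch.set_index("patient_id").loc["B", "change_steps"] == 0.0

    def test_only_cohort_patients_emitted(self):
        ch = ta.change_from_baseline(self._periods(), ["A"], "week16")
        assert list(ch["patient_id"]) == ["A"]


def _fit_dataset(n=50, seed=4, delta=500.0):
    ds = syn.simulate_outcome_dataset(syn.CohortConfig(n_patients=n, seed=seed),
                                      delta=delta, p_missing_week8=0.0)
    cohort = ta.build_analysis_cohort(ds.periods)
    ch = ta.change_from_baseline(ds.periods, cohort["week16"], "week16")
    return ds, ch


class TestAncovaEffect:
    def test_matches_normal_equations_oracle(self):
        """Coefficient and SE agree with an independent X'X beta = X'y solve."""
        ds, ch = _fit_dataset()
        eff = ta.ancova_effect(ch, ds.covariates, "steps", "week16")
        X, y = ta.build_design(ch, ds.covariates, "steps")
        Xm, ym = X.to_numpy(), y.to_numpy()
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ ym)
        resid = ym - Xm @ beta
        dof = Xm.shape[0] - Xm.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(Xm.T @ Xm)
        j = list(X.columns).index("arm")
        assert eff.difference == pytest.approx(beta[j], rel=1e-8)
        assert eff.se == pytest.approx(np.sqrt(cov[j, j]), rel=1e-8)
        tq = stats.t.ppf(0.975, dof)
        assert eff.ci_upper - eff.difference == pytest.approx(tq * eff.se, rel=1e-10)

    def test_no_covariates_equals_difference_in_means(self):
        ds, ch = _fit_dataset()
        eff = ta.ancova_effect(ch, ds.covariates, "steps", "week16",
                               covariate_set=())
        merged = ch.merge(ds.covariates, on="patient_id")
        treat = merged["arm"] == "dapagliflozin"
        closed_form = (merged.loc[treat, "change_steps"].mean()
                       - merged.loc[~treat, "change_steps"].mean())
        assert eff.difference == pytest.approx(closed_form, abs=1e-10)

    def test_identical_arms_give_zero_difference(self):
        ds, ch = _fit_dataset(delta=0.0)
        merged = ch.merge(ds.covariates[["patient_id", "arm"]], on="patient_id")
        # mirror the data so both arms see exactly the same outcome values
        flipped = merged.copy()
        flipped["patient_id"] = merged["patient_id"] + "_m"
        cov = ds.covariates.copy()
        cov_m = cov.copy()
        cov_m["patient_id"] = cov["patient_id"] + "_m"
        cov_m["arm"] = np.where(cov["arm"] == "placebo", "dapagliflozin",
                                "placebo")
        ch2 = pd.concat([merged, flipped]).drop(columns="arm").reset_index(drop=True)
        cov2 = pd.concat([cov, cov_m]).reset_index(drop=True)
        eff = ta.ancova_effect(ch2, cov2, "steps", "week16", covariate_set=())
        assert eff.difference == pytest.approx(0.0, abs=1e-9)
        assert eff.ci_lower == pytest.approx(-eff.ci_upper, abs=1e-9)

    def test_rescaling_equivariance(self):
        ds, ch = _fit_dataset()
        eff = ta.ancova_effect(ch, ds.covariates, "steps", "week16")
        c = 3.5
        ch_scaled = ch.copy()
        ch_scaled["change_steps"] *= c
        ch_scaled["baseline_steps"] *= c
        eff_s = ta.ancova_effect(ch_scaled, ds.covariates, "steps", "week16")
        assert eff_s.difference == pytest.approx(c * eff.difference, rel=1e-9)
        assert eff_s.ci_lower == pytest.approx(c * eff.ci_lower, rel=1e-9)
        assert eff_s.ci_upper == pytest.approx(c * eff.ci_upper, rel=1e-9)

    def test_single_trial_cohort_drops_trial_term(self):
        ds, ch = _fit_dataset(n=120, seed=9)
        reduced = ds.covariates.loc[ds.covariates["trial"] == "Reduced",
                                    "patient_id"]
        eff = ta.ancova_effect(ch[ch["patient_id"].isin(reduced)],
                               ds.covariates, "steps", "week16",
                               cohort_label="Reduced")
        assert np.isfinite(eff.difference)

    def test_too_few_patients_rejected(self):
        ds, ch = _fit_dataset()
        with pytest.raises(ValueError, match="2 patients per arm"):
            ta.ancova_effect(ch.iloc[:2], ds.covariates, "steps", "week16")

    def test_rank_deficiency_names_columns(self):
        ds, ch = _fit_dataset()
        ch2 = ch.copy()
        ch2["baseline_steps"] = 1.0  # duplicates the intercept
        with pytest.raises(ValueError, match="baseline_steps"):
            ta.ancova_effect(ch2, ds.covariates, "steps", "week16",
                             covariate_set=("baseline",))

    def test_uncorrelated_covariate_leaves_estimate_stable(self):
        ds, ch = _fit_dataset(n=10000, seed=30)
        full = ta.ancova_effect(ch, ds.covariates, "steps", "week16",
                                covariate_set=("baseline", "bmi"))
        slim = ta.ancova_effect(ch, ds.covariates, "steps", "week16",
                                covariate_set=("baseline",))
        assert full.difference == pytest.approx(slim.difference, abs=3 * full.se)


class TestInteractionTest:
    def test_single_trial_rejected(self):
        ds, ch = _fit_dataset(n=120, seed=9)
        reduced = ds.covariates.loc[ds.covariates["trial"] == "Reduced",
                                    "patient_id"]
        with pytest.raises(ValueError, match="both trials"):
            ta.interaction_test(ch[ch["patient_id"].isin(reduced)],
                                ds.covariates, "steps")

    def test_strong_heterogeneity_detected(self):
        """3-SE between-trial difference in the injected effect: median
        interaction p over replicates falls below 0.05."""
        pvals = []
        for seed in range(25):
            ds = syn.simulate_outcome_dataset(
                syn.CohortConfig(n_patients=400, seed=100 + seed),
                delta_by_trial={"Reduced": 0.0, "Preserved": 2400.0},
                p_missing_week8=0.0)
            cohort = ta.build_analysis_cohort(ds.periods)
            ch = ta.change_from_baseline(ds.periods, cohort["week16"], "week16")
            pvals.append(ta.interaction_test(ch, ds.covariates, "steps"))
        assert np.median(pvals) < 0.05


class TestReport:
    def test_empty_table_keeps_headers(self):
        table = ta.report([])
        assert list(table.columns)[:3] == ["outcome", "timepoint", "cohort"]
        assert len(table) == 0

    def test_row_formatting_and_rounding(self):
        eff = ta.EffectEstimate(
            outcome="steps", timepoint="week16", cohort="pooled",
            n_treat=107, n_placebo=104, mean_change_treat=88.4,
            sd_change_treat=1945.2, mean_change_placebo=-846.1,
            sd_change_placebo=2350.0, difference=777.6, se=273.0,
            ci_lower=239.6, ci_upper=1315.4, p_value=0.005)
        row = ta.report([eff]).iloc[0]
        assert row["difference"] == 778
        assert row["ci_95"] == "(240–1315)"

    def test_json_round_trip_lossless(self, tmp_path):
        ds, ch = _fit_dataset()
        eff = ta.ancova_effect(ch, ds.covariates, "steps", "week16")
        path = tmp_path / "effects.json"
        ta.effects_to_json([eff], path)
        back = ta.effects_from_json(path)[0]
        assert back == eff
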