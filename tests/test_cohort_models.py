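"""Cohort construction and Cox partial-likelihood fitting."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import errors
from mrmediate.cohort_models import (
    MODEL1_COVARIATES,
    MODEL2_COVARIATES,
    CoxModelSpec,
    assign_quartiles,
    compute_follow_up,
    fit_cox,
    per_sd,
    ph_check,
    run_model_suite,
    sensitivity_exclude_first_year,
)
from mrmediate.synthetic_data import CohortSimConfig, simulate_cohort


class TestFollowUp:
    def test_diagnosis_is_event(self):
        t, e = compute_follow_up("2010-01-01", "2018-12-31", diagnosis_date="2015-01-01")
        assert t == pytest.approx(5.0, abs=0.01)
        assert e is True

    def test_administrative_censoring(self):
        t, e = compute_follow_up("2013-06-01", "2018-12-31")
        assert t == pytest.approx(5.58, abs=0.01)
        assert e is False

    def test_earliest_date_wins_death_censors(self):
        t, e = compute_follow_up(
            "2010-01-01", "2018-12-31",
            diagnosis_date="2015-06-01", death_date="2014-06-01",
        )
        assert e is False
        assert t == pytest.approx((pd.Timestamp("2014-06-01") - pd.Timestamp("2010-01-01")).days / 365.25)

    def test_negative_follow_up_rejected(self):
        with pytest.raises(errors.InputError):
            compute_follow_up("2015-01-01", "2018-12-31", diagnosis_date="2014-01-01")


class TestExposureCoding:
    def test_per_sd_unit_variance_input_unchanged(self):
        scaled, sd = per_sd([1.0, 2.0, 3.0])
        assert sd == pytest.approx(1.0)
        assert np.allclose(scaled, [1, 2, 3])

    def test_per_sd_scale_invariance(self, rng):
        vals = rng.normal(10, 3, 100)
        scaled, sd = per_sd(vals)
        scaled10, sd10 = per_sd(vals * 10)
        assert sd10 == pytest.approx(10 * sd)
        assert np.allclose(scaled10, scaled)

    def test_per_sd_zero_variance_rejected(self):
        with pytest.raises(errors.InputError):
            per_sd([2.0, 2.0, 2.0])

    def test_quartiles_of_one_to_eight(self):
        qa = assign_quartiles(list(range(1, 9)))
        groups = {q: [v for v, lab in zip(range(1, 9), qa.labels) if lab == q]
                  for q in ("Q1", "Q2", "Q3", "Q4")}
        assert groups == {"Q1": [1, 2], "Q2": [3, 4], "Q3": [5, 6], "Q4": [7, 8]}

    def test_quartiles_degenerate_rejected(self):
        with pytest.raises(errors.InputError):
            assign_quartiles([5.0] * 10)

    def test_quartile_cut_points_match_normal_theory(self, default_cohort):
        # mediator ~ Normal(273.1, ~75): quartile cuts near mean +/- 0.674 sd
        ua = default_cohort["ua"]
        qa = assign_quartiles(ua)
        m, s = ua.mean(), ua.std(ddof=1)
        assert qa.cut_points[0] == pytest.approx(m - 0.6745 * s, abs=0.05 * s)
        assert qa.cut_points[1] == pytest.approx(m, abs=0.05 * s)
        assert qa.cut_points[2] == pytest.approx(m + 0.6745 * s, abs=0.05 * s)

    def test_mediator_sd_near_generator_target(self, default_cohort):
        _, sd = per_sd(default_cohort["ua"])
        assert sd == pytest.approx(75.0, rel=0.03)


class TestFitCox:
    def test_null_model_risk_set_counting(self):
        # three distinct event times, all events: log PL = -log 6
        df = pd.DataFrame({"time_years": [1.0, 2.0, 3.0], "event": [1, 1, 1]})
        fit = fit_cox(df, [])
        assert fit.loglik == pytest.approx(-np.log(6), abs=1e-12)
        assert fit.n_events == 3

    def test_grid_search_oracle_five_subjects(self, five_subject_cox):
        fit = fit_cox(five_subject_cox, ["x"])

        def neg_pl(beta):
            # hand-written Efron/Breslow partial likelihood (no ties here)
            d = five_subject_cox.sort_values("time_years")
            x = d["x"].to_numpy()
            e = d["event"].to_numpy(bool)
            ll = 0.0
            for i in range(len(d)):
                if e[i]:
                    ll += beta * x[i] - np.log(np.exp(beta * x[i:]).sum())
            return ll

        grid = np.arange(-3, 3, 1e-4)
        best = grid[np.argmax([neg_pl(b) for b in grid])]
        assert fit.params["x"] == pytest.approx(best, abs=1e-4)

    def test_matches_lifelines(self, small_cohort):
        from lifelines import CoxPHFitter

        cols = ["bmi", "ua", "age", "smoking"]
        fit = fit_cox(small_cohort, cols)
        cph = CoxPHFitter().fit(
            small_cohort[cols + ["time_years", "event"]], "time_years", "event"
        )
        # lifelines stops at a looser score tolerance than this solver
        assert np.allclose(fit.params.to_numpy(), cph.params_.to_numpy(), atol=5e-4)
        assert np.allclose(fit.se.to_numpy(), cph.standard_errors_.to_numpy(), atol=5e-4)

    def test_efron_equals_breslow_without_ties(self, five_subject_cox):
        fe = fit_cox(five_subject_cox, ["x"], ties="efron")
        fb = fit_cox(five_subject_cox, ["x"], ties="breslow")
        assert fe.params["x"] == pytest.approx(fb.params["x"], abs=1e-10)
        assert fe.loglik == pytest.approx(fb.loglik, abs=1e-10)

    def test_efron_differs_from_breslow_with_ties(self, rng):
        n = 400
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(np.exp(-0.5 * x)) * 4)  # day-level ties
        e = (t <= 8).astype(int)
        df = pd.DataFrame({"x": x, "time_years": np.minimum(t, 8), "event": e})
        fe = fit_cox(df, ["x"], ties="efron")
        fb = fit_cox(df, ["x"], ties="breslow")
        assert abs(fe.params["x"] - fb.params["x"]) > 1e-4

    def test_reparameterization_invariance(self, small_cohort):
        fit = fit_cox(small_cohort, ["bmi"])
        scaled = small_cohort.assign(bmi=small_cohort["bmi"] * 10)
        fit10 = fit_cox(scaled, ["bmi"])
        assert fit10.params["bmi"] == pytest.approx(fit.params["bmi"] / 10, rel=1e-6)

    def test_score_norm_small_at_optimum(self, small_cohort):
        fit = fit_cox(small_cohort, ["bmi", "ua", "age"])
        assert fit.score_norm < 1e-6

    def test_covariance_symmetric_psd(self, small_cohort):
        fit = fit_cox(small_cohort, ["bmi", "ua", "age", "smoking"])
        cov = fit.cov.to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time_years": [1.0, 2.0], "event": [0, 0], "x": [0.0, 1.0]})
        with pytest.raises(errors.InputError):
            fit_cox(df, ["x"])

    def test_separation_raises_convergence_error(self):
        # perfect separation: all events in one covariate group
        df = pd.DataFrame({
            "x": [1.0] * 20 + [0.0] * 20,
            "time_years": list(np.linspace(0.1, 2, 20)) + [5.0] * 20,
            "event": [1] * 20 + [0] * 20,
        })
        with pytest.raises(errors.ConvergenceError):
            fit_cox(df, ["x"])

    def test_complete_case_rule(self, small_cohort):
        df = small_cohort.copy()
        df.loc[df.index[:500], "bmi"] = np.nan
        fit = fit_cox(df, ["bmi", "age"])
        assert fit.n_used == len(df) - 500


class TestSensitivity:
    def test_first_year_cases_removed_censored_kept(self):
        df = pd.DataFrame({
            "time_years": [0.5, 0.5, 2.0, 0.9],
            "event": [1, 0, 1, 1],
        })
        out = sensitivity_exclude_first_year(df)
        assert len(out) == 2
        assert out["time_years"].tolist() == [0.5, 2.0]

    def test_identity_without_first_year_cases(self, small_cohort):
        df = small_cohort[~((small_cohort.event == 1) & (small_cohort.time_years < 1))]
        assert len(sensitivity_exclude_first_year(df)) == len(df)

    def test_injected_first_year_cases_counted(self, small_cohort):
        df = small_cohort.copy()
        extra = df.iloc[:10].copy()
        extra["time_years"] = 0.3
        extra["event"] = 1
        df = pd.concat([df, extra], ignore_index=True)
        before_early = ((df.event == 1) & (df.time_years < 1)).sum()
        out = sensitivity_exclude_first_year(df)
        assert len(df) - len(out) == before_early >= 10


class TestPhCheck:
    def test_type_one_error_near_nominal(self):
        # proportional hazards true: flag rate over 200 sims near 5%
        rng = np.random.default_rng(31)
        flags = 0
        n_sims = 200
        for _ in range(n_sims):
            n = 400
            x = rng.normal(size=n)
            t = rng.exponential(np.exp(-0.4 * x))
            e = (t <= 2).astype(int)
            df = pd.DataFrame({"x": x, "time_years": np.minimum(t, 2), "event": e})
            fit = fit_cox(df, ["x"])
            if ph_check(fit, df)["x"] < 0.05:
                flags += 1
        assert 0.01 <= flags / n_sims <= 0.12

    def test_time_varying_effect_flagged(self):
        # x = 1 hazard rises steeply with time, x = 0 constant -> violation
        rng = np.random.default_rng(32)
        n = 2000
        x = rng.binomial(1, 0.5, n).astype(float)
        t = np.where(x == 1, rng.weibull(4, n) * 1.5, rng.exponential(1.2, n))
        e = (t <= 2).astype(int)
        df = pd.DataFrame({"x": x, "time_years": np.minimum(t, 2), "event": e})
        fit = fit_cox(df, ["x"])
        assert ph_check(fit, df)["x"] < 0.01

    def test_zero_covariate_model_empty(self):
        df = pd.DataFrame({"time_years": [1.0, 2.0, 3.0], "event": [1, 1, 0]})
        fit = fit_cox(df, [])
        assert ph_check(fit, df).empty


@pytest.fixture(scope="module")
def suite(small_cohort):
    return run_model_suite(small_cohort)


class TestModelSuite:
    def test_adjustment_sets_nested(self):
        spec1 = CoxModelSpec("bmi", model=1).covariates()
        spec2 = CoxModelSpec("bmi", model=2).covariates()
        spec3 = CoxModelSpec("bmi", model=3, co_adjust="ua").covariates()
        assert set(spec1) < set(spec2) < set(spec3)
        assert spec1 == MODEL1_COVARIATES and spec2 == MODEL2_COVARIATES

    def test_quartile_reference_group_hr_one(self, suite):
        q1 = suite[(suite.coding == "quartile") & (suite.stratum == "Q1")]
        assert (q1.hr == 1.0).all()

    def test_person_years_partition(self, suite, small_cohort):
        total = small_cohort["time_years"].sum()
        q = suite[(suite.coding == "quartile") & (suite.model == 1)]
        assert q.person_years.sum() == pytest.approx(total, rel=1e-12)
        b = suite[(suite.coding == "binary") & (suite.model == 1)]
        assert b.person_years.sum() == pytest.approx(total, rel=1e-12)

    def test_structure_covers_models_and_codings(self, suite):
        assert set(suite.model) == {1, 2, 3}
        assert set(suite.coding) == {"per_sd", "binary", "quartile"}
        assert set(suite.variable) == {"bmi", "ua"}

    def test_adjusted_hr_attenuated_by_mediator(self, suite):
        # model 3 adds the mediator: direct BMI effect below total (model 2)
        m2 = suite[(suite.variable == "bmi") & (suite.coding == "per_sd") & (suite.model == 2)]
        m3 = suite[(suite.variable == "bmi") & (suite.coding == "per_sd") & (suite.model == 3)]
        assert float(m3.hr.iloc[0]) < float(m2.hr.iloc[0])


class TestNullRecovery:
    def test_zero_effect_generator_ci_covers_one(self):
        cfg = CohortSimConfig(n_subjects=6000, baseline_rate=4e-3,
                              theta1=0.0, theta2=0.0, seed=77)
        cohort = simulate_cohort(cfg)
        scaled, _ = per_sd(cohort["bmi"])
        fit = fit_cox(cohort.assign(bmi_sd=scaled), ["bmi_sd"] + MODEL1_COVARIATES)
        s = fit.summary().loc["bmi_sd"]
        assert s.ci_low < 1.0 < s.ci_high
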