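"""Prognostic regression contracts: linear, logistic, subgroup, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from ssnhl_ipta.prognosis import (
    CollinearityError,
    ModelSpec,
    default_linear_spec,
    duration_subgroup_regressions,
    fit_linear_prognostic,
    fit_logistic_prognostic,
    full_recovery_spec,
    partial_vs_none_spec,
    sensitivity_analysis,
)


def toy_frame(n=200, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "flag": rng.integers(0, 2, size=n),
        }
    )
    df["y"] = 3.0 - 2.0 * df.x1 + 0.5 * df.x2 + 4.0 * df.flag
    return df


class TestLinear:
    def test_noiseless_coefficients_recovered_exactly(self):
        df = toy_frame()
        res = fit_linear_prognostic(df, ModelSpec("y", ("x1", "x2", "flag")))
        assert res.coefficient("x1")["estimate"] == pytest.approx(-2.0, abs=1e-10)
        assert res.coefficient("x2")["estimate"] == pytest.approx(0.5, abs=1e-10)
        assert res.coefficient("flag")["estimate"] == pytest.approx(4.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(1)
        df = toy_frame(80, 1)
        df["y"] = df["y"] + rng.normal(0, 2, size=80)
        res = fit_linear_prognostic(df, ModelSpec("y", ("x1", "x2")))
        X = np.column_stack([np.ones(80), df.x1, df.x2])
        beta = np.linalg.solve(X.T @ X, X.T @ df.y.to_numpy())
        assert res.coefficient("x1")["estimate"] == pytest.approx(beta[1])
        assert res.coefficient("x2")["estimate"] == pytest.approx(beta[2])

    def test_ci_brackets_estimate(self):
        df = toy_frame(80, 2)
        df["y"] = df["y"] + np.random.default_rng(2).normal(0, 2, size=80)
        res = fit_linear_prognostic(df, ModelSpec("y", ("x1", "x2", "flag")))
        assert (res.table["ci_low"] <= res.table["estimate"]).all()
        assert (res.table["estimate"] <= res.table["ci_high"]).all()

    def test_location_equivariance(self):
        df = toy_frame(100, 3)
        df["y"] = df["y"] + np.random.default_rng(3).normal(0, 1, size=100)
        res1 = fit_linear_prognostic(df, ModelSpec("y", ("x1", "flag")))
        df2 = df.assign(y=df.y + 50)
        res2 = fit_linear_prognostic(df2, ModelSpec("y", ("x1", "flag")))
        for term in ("x1", "flag"):
            assert res1.coefficient(term)["estimate"] == pytest.approx(
                res2.coefficient(term)["estimate"])
        assert res2.coefficient("Intercept")["estimate"] == pytest.approx(
            res1.coefficient("Intercept")["estimate"] + 50)

    def test_collinearity_names_offender(self):
        df = toy_frame(50, 4)
        df["x3"] = 2 * df["x1"]
        with pytest.raises(CollinearityError, match="x3|x1"):
            fit_linear_prognostic(df, ModelSpec("y", ("x1", "x2", "x3")))

    def test_more_parameters_than_rows_rejected(self):
        df = toy_frame(3, 5)
        with pytest.raises(ValueError, match="rows"):
            fit_linear_prognostic(df, ModelSpec("y", ("x1", "x2", "flag")))


class TestLogistic:
    def test_two_by_two_matches_cross_product_ratio(self):
        # 2x2 table: exposed/unexposed x outcome, OR = ad/bc
        a, b, c, d = 30, 10, 20, 40  # exposed-yes, exposed-no, unexposed-yes, unexposed-no
        rows = ([{"exposed": 1, "y": 1}] * a + [{"exposed": 1, "y": 0}] * b
                + [{"exposed": 0, "y": 1}] * c + [{"exposed": 0, "y": 0}] * d)
        df = pd.DataFrame(rows)
        res = fit_logistic_prognostic(df, ModelSpec("y", ("exposed",), family="logistic"))
        assert res.coefficient("exposed")["estimate"] == pytest.approx(
            (a * d) / (b * c), rel=1e-6)

    def test_null_covariate_or_near_one(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"x": rng.normal(size=20000)})
        df["y"] = (rng.random(20000) < 0.3).astype(int)
        res = fit_logistic_prognostic(df, ModelSpec("y", ("x",), family="logistic"))
        assert res.coefficient("x")["estimate"] == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_flagged(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "y": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        res = fit_logistic_prognostic(df, ModelSpec("y", ("x",), family="logistic"))
        assert res.separation_flag

    def test_partial_vs_none_excludes_full(self, study_table):
        spec = partial_vs_none_spec("ipta")
        res = fit_logistic_prognostic(study_table, spec)
        n_full = int((study_table["category_ipta"] == "full").sum())
        assert res.n == len(study_table) - n_full


class TestDurationSubgroups:
    def test_crude_slope_matches_simple_regression(self, study_table):
        import statsmodels.formula.api as smf

        out = duration_subgroup_regressions(study_table)
        for arm, mask in (("treated", 1), ("untreated", 0)):
            sub = study_table[study_table.treated == mask]
            expected = smf.ols("recovery_ipta ~ duration_days", sub).fit().params[
                "duration_days"]
            got = out[arm]["crude"].coefficient("duration_days")["estimate"]
            assert got == pytest.approx(expected)

    def test_adjusted_close_to_crude_under_orthogonal_design(self):
        # adjustment covariates independent of duration: slopes agree in expectation
        rng = np.random.default_rng(7)
        n = 4000
        df = pd.DataFrame(
            {
                "duration_days": rng.exponential(5, n),
                "age_group": rng.choice(["young", "middle_aged", "older", "elderly"], n),
                "degree": rng.choice(["no_mild", "moderate", "severe", "profound"], n),
                "hypertension": rng.integers(0, 2, n),
                "diabetes": rng.integers(0, 2, n),
                "tinnitus": rng.integers(0, 2, n),
                "dizziness": rng.integers(0, 2, n),
                "treated": np.r_[np.ones(n // 2), np.zeros(n - n // 2)].astype(int),
            }
        )
        df["recovery_ipta"] = 30 - 0.8 * df.duration_days + rng.normal(0, 10, n)
        out = duration_subgroup_regressions(df)
        for arm in ("treated", "untreated"):
            crude = out[arm]["crude"].coefficient("duration_days")["estimate"]
            adjusted = out[arm]["adjusted"].coefficient("duration_days")["estimate"]
            assert adjusted == pytest.approx(crude, abs=0.05)

    def test_empty_arm_rejected(self, study_table):
        allt = study_table.assign(treated=1)
        with pytest.raises(ValueError, match="empty treatment arm"):
            duration_subgroup_regressions(allt)

    def test_zero_slope_ci_covers_zero_in_most_seeds(self):
        from ssnhl_ipta.simulate import default_config, generate_cohort
        from ssnhl_ipta.pipeline import build_analysis_table

        cfg = default_config(recovery={"duration_treated_db_per_day": 0.0,
                                       "duration_untreated_db_per_day": 0.0})
        covered = 0
        for seed in range(20):
            table = build_analysis_table(generate_cohort(cfg, seed=100 + seed).records)
            fit = duration_subgroup_regressions(table)["treated"]["crude"]
            row = fit.coefficient("duration_days")
            covered += row["ci_low"] <= 0 <= row["ci_high"]
        assert covered >= 18  # 95% CI: expect ~19/20


class TestSensitivity:
    def test_rule_matching_nobody_is_noop(self, study_table):
        table = study_table.assign(identified_etiology=0)
        primary = fit_linear_prognostic(table, default_linear_spec("ipta"))
        sens = sensitivity_analysis(table, "exclude_identified_etiology")
        pd.testing.assert_frame_equal(primary.table, sens.table)
        assert sens.n == primary.n

    def test_reports_n_excluded(self, study_table):
        sens = sensitivity_analysis(study_table, "exclude_pre_audiogram_treated")
        n_flagged = int(study_table["pretreated_before_audiogram"].sum())
        assert sens.n_excluded == n_flagged
        assert sens.n == len(study_table) - n_flagged

    def test_degenerate_covariate_reported_absent(self, study_table):
        # excluding every dizzy patient leaves dizziness without variation:
        # the term is dropped and reported, not silently zeroed
        table = study_table.assign(
            identified_etiology=study_table["dizziness"])
        with pytest.warns(UserWarning, match="dropped"):
            sens = sensitivity_analysis(table, "exclude_identified_etiology")
        assert "dizziness" in sens.dropped_terms
        assert not sens.table["term"].str.contains("dizziness").any()

    def test_unknown_rule_rejected(self, study_table):
        with pytest.raises(KeyError, match="unknown sensitivity rule"):
            sensitivity_analysis(study_table, "exclude_left_handed")

    def test_emptying_rule_rejected(self, study_table):
        table = study_table.assign(identified_etiology=1)
        with pytest.raises(ValueError, match="empties"):
            sensitivity_analysis(table, "exclude_identified_etiology")


class TestPlantedEffectsSingleCohort:
    def test_dizziness_direction_and_rough_size(self, study_table):
        res = fit_linear_prognostic(study_table, default_linear_spec("ipta"))
        b = res.coefficient("dizziness")["estimate"]
        assert -25 < b < -5  # single cohort: sign and order of magnitude

    def test_deterministic_limit_recovers_intercept_exactly(self):
        # no noise, no effects, 5 dB-aligned intercept, no gradient: every
        # patient's measured iPTA recovery equals the planted predictor
        from ssnhl_ipta.simulate import default_config, generate_cohort
        from ssnhl_ipta.pipeline import build_analysis_table

        cfg = default_config(
            n=60,
            recovery={
                "intercept_db": 40.0, "dizziness_db": 0.0, "tinnitus_db": 0.0,
                "duration_treated_db_per_day": 0.0, "duration_untreated_db_per_day": 0.0,
                "noise_sd": 0.0, "gradient_db_per_step": 0.0,
                "high_freq_penalty_db": 0.0, "followup_noise_sd": 0.0,
            },
            lesion={"severity_lesion_db": {
                "no_mild": (55.0, 60.0), "moderate": (55.0, 60.0),
                "severe": (60.0, 65.0), "profound": (65.0, 70.0)}},
        )
        table = build_analysis_table(generate_cohort(cfg, seed=2).records)
        assert np.allclose(table["recovery_ipta"], 40.0)
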