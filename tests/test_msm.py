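"""Weighted discrete-time hazard fits, Cox comparators and the spline
dose–response model."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from msmcvd import (SimParams, compute_weights, fit_cox_time_fixed,
                    fit_cox_time_varying, fit_msm, fit_naive_time_varying,
                    fit_treatment_models, simulate_person_periods,
                    spline_dose_response, standardized_regime_hr)
from msmcvd.msm import EstimationError, SplineSpec, spline_basis
from msmcvd.iptw import dose_exposure_weights


class TestMSMReductions:
    def test_unit_weights_equal_unweighted_fit(self, medium_pp):
        a = fit_msm(medium_pp, weights=None)
        b = fit_msm(medium_pp, weights=np.ones(len(medium_pp)))
        np.testing.assert_array_equal(a.fit.params, b.fit.params)

    def test_single_interval_reduces_to_plain_logistic(self, medium_pp):
        pp0 = medium_pp[medium_pp["k"] == 0]
        fit = fit_msm(pp0, weights=None)
        X = np.column_stack([
            np.ones(len(pp0)), pp0["A"], pp0["female"], pp0["age_at_index"],
        ])
        ref = sm.Logit(pp0["Y"].to_numpy(), X).fit(disp=0)
        np.testing.assert_allclose(fit.fit.params, ref.params, atol=1e-8)

    def test_cluster_se_not_smaller_than_model_se_when_weighted(self,
                                                                medium_pp):
        models = fit_treatment_models(medium_pp)
        ws = compute_weights(medium_pp, models)
        fit = fit_msm(medium_pp, weights=ws)
        i = fit.fit.names.index("A")
        assert fit.fit.cov[i, i] >= 0.8 * fit.fit.cov_model[i, i]

    def test_zero_events_raise(self, medium_pp):
        pp = medium_pp.assign(Y=0)
        with pytest.raises(EstimationError):
            fit_msm(pp)

    def test_hr_frame_consistency(self, medium_pp):
        fit = fit_msm(medium_pp, weights=None)
        hr = fit.hazard_ratios()
        assert (hr["ci_low"] <= hr["hr"]).all()
        assert (hr["hr"] <= hr["ci_high"]).all()
        assert hr.loc["A", "hr"] == pytest.approx(
            np.exp(fit.coefficients["A"]))

    def test_null_model_standardized_hr_is_one(self, medium_pp):
        fit = fit_msm(medium_pp, weights=None)
        fit.fit.params[fit.fit.names.index("A")] = 0.0
        assert standardized_regime_hr(fit, medium_pp) == pytest.approx(1.0)


def _exponential_survival_frame(n, hr, seed):
    """Point-exposure exponential survival with no confounding."""
    rng = np.random.default_rng(seed)
    exposed = rng.random(n) < 0.5
    rate = 0.01 * np.where(exposed, hr, 1.0)
    t = rng.exponential(1.0 / rate)
    cens = rng.uniform(20, 120, n)
    return pd.DataFrame({
        "duration_days": np.minimum(t, cens),
        "event": (t <= cens).astype(int),
        "ever_exposed": exposed.astype(int),
        "female": rng.integers(0, 2, n),
        "age_at_index": rng.normal(40, 10, n),
    })


class TestCoxComparators:
    def test_time_fixed_recovers_true_hr(self):
        df = _exponential_survival_frame(10000, hr=2.0, seed=4)
        fit = fit_cox_time_fixed(df)
        row = fit.hazard_ratios().iloc[0]
        assert abs(row["log_hr"] - np.log(2.0)) < 2 * row["se_log_hr"]

    def test_constant_exposure_raises(self):
        df = _exponential_survival_frame(500, hr=2.0, seed=4)
        df["ever_exposed"] = 1
        with pytest.raises(EstimationError, match="constant"):
            fit_cox_time_fixed(df)

    def test_time_varying_reduces_to_time_fixed_for_constant_covariates(self):
        df = _exponential_survival_frame(3000, hr=1.8, seed=9)
        # split each person into 30-day episodes with constant covariates
        rows = []
        for pid, r in df.iterrows():
            edges = np.arange(0, r["duration_days"], 30.0)
            for j, s in enumerate(edges):
                e = min(s + 30.0, r["duration_days"])
                rows.append({
                    "person_id": pid, "k": j, "interval_start": s,
                    "interval_end": e, "A": r["ever_exposed"],
                    "female": r["female"], "age_at_index": r["age_at_index"],
                    "Y": int((e == r["duration_days"]) and r["event"]),
                })
        pp = pd.DataFrame(rows)
        tv = fit_cox_time_varying(pp)
        fixed = fit_cox_time_fixed(df)
        np.testing.assert_allclose(
            tv.hazard_ratios()["log_hr"].iloc[0],
            fixed.hazard_ratios()["log_hr"].iloc[0], atol=1e-6)

    def test_overlapping_intervals_rejected(self, medium_pp):
        dup = pd.concat([medium_pp, medium_pp.head(5)], ignore_index=True)
        with pytest.raises(ValueError, match="overlapping"):
            fit_cox_time_varying(dup)

    def test_discrete_time_agrees_with_cox_for_rare_outcomes(self):
        pp = simulate_person_periods(
            SimParams(n_persons=20000, treatment_effect_on_severity=0.0,
                      severity_effect_on_treatment=0.0, seed=31))
        logit_fit = fit_msm(pp, weights=None)
        cox_fit = fit_cox_time_varying(pp)
        a = logit_fit.hazard_ratios()["log_hr"].iloc[0]
        b = cox_fit.hazard_ratios()["log_hr"].iloc[0]
        assert abs(a - b) / abs(b) < 0.05

    def test_feedback_biases_conditional_models(self):
        """Under treatment-confounder feedback the covariate-adjusted
        time-varying fit is materially below the weighted MSM estimate."""
        pp = simulate_person_periods(SimParams(n_persons=30000, seed=14))
        models = fit_treatment_models(pp)
        ws = compute_weights(pp, models)
        msm = fit_msm(pp, weights=ws, exposure_cols=("A", "A_prev"))
        naive = fit_naive_time_varying(pp)
        assert standardized_regime_hr(naive, pp) \
            < standardized_regime_hr(msm, pp)


class TestClassExposure:
    def test_per_class_indicator_fit(self, small_params):
        """The claims pipeline carries per-class exposure indicators that
        fit as a multi-column exposure specification."""
        from msmcvd import apply_eligibility, build_person_periods, \
            generate_cohort

        raw = generate_cohort(small_params)
        cohort, _ = apply_eligibility(raw)
        pp = build_person_periods(raw, cohort)
        fit = fit_msm(pp, weights=None,
                      exposure_cols=("A_SSRI", "A_SNRI", "A_TCA"),
                      min_events=1)
        hr = fit.hazard_ratios()
        assert list(hr.index) == ["A_SSRI", "A_SNRI", "A_TCA"]
        assert (hr["hr"] > 0).all()


class TestSpline:
    def test_reference_hr_exactly_one_at_dose_zero(self, medium_pp):
        _, curve = spline_dose_response(medium_pp, None)
        assert curve.loc[0, "cum_ddd"] == 0.0
        assert curve.loc[0, "hr"] == pytest.approx(1.0)
        assert curve.loc[0, "ci_low"] == pytest.approx(1.0)

    def test_basis_dimension(self, medium_pp):
        fit, _ = spline_dose_response(medium_pp, None)
        spec = SplineSpec()
        # full clamped basis = interior knots + degree + 1; one member is
        # absorbed by the intercept
        assert len(fit.exposure_cols) == (
            len(spec.knot_percentiles) + spec.degree + 1 - 1)

    def test_basis_rows_at_zero_are_zero(self, medium_pp):
        spec = SplineSpec()
        x_max = float(np.log1p(medium_pp["cum_ddd"].max()))
        from msmcvd.msm import _spline_knots
        knots = _spline_knots(medium_pp["cum_ddd"], spec, x_max)
        B = spline_basis(np.array([0.0]), knots, spec.degree, x_max)
        assert (B.to_numpy() == 0).all()

    def test_linear_truth_within_spline_band(self):
        """When the log-dose effect is linear, the spline curve's CI band
        contains the linear fit over the bulk of the dose range."""
        pp = simulate_person_periods(SimParams(n_persons=30000, seed=41))
        dws = dose_exposure_weights(pp)
        lin = fit_msm(pp.assign(log_cum_ddd=np.log1p(pp["cum_ddd"])),
                      weights=dws, exposure_cols=("log_cum_ddd",))
        slope = lin.coefficients["log_cum_ddd"]
        _, curve = spline_dose_response(pp, dws)
        bulk = curve[curve["cum_ddd"] <= np.quantile(pp["cum_ddd"], 0.95)]
        lin_hr = np.exp(slope * np.log1p(bulk["cum_ddd"]))
        inside = ((lin_hr >= bulk["ci_low"]) & (lin_hr <= bulk["ci_high"]))
        assert inside.mean() > 0.8

    def test_too_few_distinct_doses_rejected(self, medium_pp):
        pp = medium_pp.assign(cum_ddd=(medium_pp["A"] * 10.0))
        with pytest.raises(EstimationError, match="distinct dose"):
            spline_dose_response(pp, None)
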