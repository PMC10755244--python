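"""IPT weight construction: model fitting, cumulative products, truncation,
dose-level weights and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msmcvd import (SimParams, TreatmentModelSpec, compute_weights,
                    dose_exposure_weights, fit_treatment_models,
                    simulate_person_periods, truncate_weights,
                    weight_diagnostics)
from msmcvd.iptw import WeightSet, _weights_from_probs
from msmcvd.simulate import (_TREAT_FEMALE, _TREAT_INTERCEPT,
                             _TREAT_PERSISTENCE)


def _toy_pp(p_num_obs, p_den_obs, person_id=0):
    k = np.arange(len(p_num_obs))
    return pd.DataFrame({"person_id": person_id, "k": k})


class TestWeightProducts:
    def test_hand_arithmetic_two_intervals(self):
        pp = _toy_pp([0.5, 0.5], [0.8, 0.4])
        ws = _weights_from_probs(pp, np.array([0.5, 0.5]),
                                 np.array([0.8, 0.4]), kind="binary")
        assert ws.frame["sw"].iloc[-1] == pytest.approx(0.78125)
        assert ws.frame["w"].iloc[-1] == pytest.approx(3.125)

    def test_numerator_equals_denominator_gives_unit_weights(self, medium_pp):
        spec = TreatmentModelSpec(time_varying_covariates=())
        models = fit_treatment_models(medium_pp, spec)
        ws = compute_weights(medium_pp, models)
        np.testing.assert_allclose(ws.frame["sw"], 1.0, atol=1e-10)

    def test_matches_brute_force_product(self):
        """On a 4-interval cohort the vectorized cumulative products match an
        independent per-person loop to near machine precision."""
        pp = simulate_person_periods(SimParams(n_persons=500, n_intervals=4,
                                               seed=12))
        models = fit_treatment_models(pp)
        ws = compute_weights(pp, models)
        p_num = models.prob_observed(pp, "numerator")
        p_den = models.prob_observed(pp, "denominator")
        df = pp[["person_id", "k"]].assign(pn=p_num, pd_=p_den)
        sw_brute, w_brute = [], []
        for _, g in df.groupby("person_id", sort=True):
            acc_sw = acc_w = 1.0
            for row in g.itertuples(index=False):
                acc_sw *= row.pn / row.pd_
                acc_w *= 1.0 / row.pd_
                sw_brute.append(acc_sw)
                w_brute.append(acc_w)
        np.testing.assert_allclose(ws.frame["sw"], sw_brute, rtol=1e-12)
        np.testing.assert_allclose(ws.frame["w"], w_brute, rtol=1e-12)

    def test_sw_equals_w_times_numerator_product(self, medium_pp):
        models = fit_treatment_models(medium_pp)
        ws = compute_weights(medium_pp, models)
        num_prod = ws.frame.groupby("person_id")["p_num_obs"].cumprod()
        np.testing.assert_allclose(ws.frame["sw"],
                                   ws.frame["w"] * num_prod, rtol=1e-12)

    def test_mean_stabilized_weight_near_one(self, medium_pp):
        models = fit_treatment_models(medium_pp)
        ws = compute_weights(medium_pp, models)
        g = ws.frame.groupby("k")["sw"]
        z = (g.mean() - 1.0) / (g.std(ddof=1) / np.sqrt(g.size()))
        assert np.abs(z).max() < 3.0


class TestTreatmentModels:
    def test_assignment_coefficient_recovery(self):
        """With the assignment model fit on its true covariate layout, the
        estimated coefficients recover the generator's within 2 SE."""
        pp = simulate_person_periods(SimParams(n_persons=50000, seed=23))
        pp["burden"] = (pp[[c for c in pp.columns if c.startswith("com_")]]
                        .sum(axis=1) + pp["psych_hosp"])
        spec = TreatmentModelSpec(baseline_covariates=("female",),
                                  time_varying_covariates=("burden",),
                                  history=("A_prev",),
                                  interval_as_categorical=False)
        models = fit_treatment_models(pp, spec)
        sf = models.denominator.summary_frame()
        p = SimParams()
        for name, truth in [("burden", p.severity_effect_on_treatment),
                            ("A_prev", _TREAT_PERSISTENCE),
                            ("female", _TREAT_FEMALE),
                            ("const", _TREAT_INTERCEPT)]:
            row = sf.loc[name]
            assert abs(row["coef"] - truth) < 2.5 * row["se"], name

    def test_single_level_interval_warns(self):
        pp = pd.DataFrame({
            "person_id": np.arange(40) % 10, "k": np.arange(40) // 10,
            "A": ([0, 1] * 15) + [1] * 10,  # last interval all treated
            "female": 0, "age_at_index": 40.0, "A_prev": 0,
            "ever_treated_prev": 0,
            **{c: 0 for c in ("com_psychotic", "com_bipolar", "com_depressive",
                              "com_anxiety", "com_somatoform", "psych_hosp")},
        })
        with pytest.warns(UserWarning, match="single observed treatment"):
            try:
                fit_treatment_models(pp)
            except Exception:
                pass  # separation may follow; the screen must fire first


class TestTruncation:
    def _ws(self, values):
        frame = pd.DataFrame({
            "person_id": np.arange(len(values)), "k": 0,
            "p_num_obs": 0.5, "p_den_obs": 0.5,
            "sw": values, "w": values,
        })
        return WeightSet(frame=frame)

    def test_identity_at_full_range(self):
        ws = self._ws(np.array([0.1, 1.0, 2.0, 50.0]))
        out = truncate_weights(ws, 0, 100)
        np.testing.assert_array_equal(out.frame["sw"], ws.frame["sw"])

    def test_percentile_clamp_hand_case(self):
        ws = self._ws(np.array([1.0, 1.0, 1.0, 100.0]))
        out = truncate_weights(ws, 10, 90)
        # 90th percentile of (1,1,1,100) with linear interpolation = 70.3
        assert out.frame["sw"].max() == pytest.approx(
            np.percentile([1, 1, 1, 100], 90))

    @given(st.lists(st.floats(0.01, 100.0), min_size=5, max_size=50))
    def test_truncation_bounds_and_variance_shrink(self, values):
        ws = self._ws(np.array(values))
        out = truncate_weights(ws, 10, 90)
        lo, hi = np.percentile(values, [10, 90])
        assert out.frame["sw"].min() >= lo - 1e-12
        assert out.frame["sw"].max() <= hi + 1e-12
        assert out.frame["sw"].var() <= ws.frame["sw"].var() + 1e-12

    def test_bad_bounds_rejected(self):
        ws = self._ws(np.ones(4))
        with pytest.raises(ValueError):
            truncate_weights(ws, 90, 10)

    def test_empty_rejected(self):
        ws = WeightSet(frame=pd.DataFrame(columns=["person_id", "k", "sw",
                                                   "w"]))
        with pytest.raises(ValueError):
            truncate_weights(ws, 1, 99)


class TestDoseWeights:
    def test_all_unexposed_gives_unit_weights(self, medium_pp):
        pp = medium_pp.assign(interval_ddd=0.0)
        ws = dose_exposure_weights(pp)
        np.testing.assert_array_equal(ws.frame["sw"], 1.0)

    def test_binary_collapse_reproduces_binary_weights(self, medium_pp):
        binary_dose = medium_pp.assign(
            interval_ddd=medium_pp["A"].astype(float))
        ws_dose = dose_exposure_weights(binary_dose, n_positive_levels=1)
        models = fit_treatment_models(medium_pp)
        ws_bin = compute_weights(medium_pp, models)
        np.testing.assert_allclose(ws_dose.frame["sw"].to_numpy(),
                                   ws_bin.frame["sw"].to_numpy(), rtol=1e-10)

    def test_multinomial_observed_level_product(self):
        """Cumulative products of hand-specified observed-level probabilities."""
        pp = _toy_pp([1, 1, 1], [1, 1, 1])
        ws = _weights_from_probs(pp, np.array([0.5, 0.3, 0.2]),
                                 np.array([0.25, 0.6, 0.4]), kind="dose")
        expected_sw = np.cumprod([0.5 / 0.25, 0.3 / 0.6, 0.2 / 0.4])
        np.testing.assert_allclose(ws.frame["sw"], expected_sw, rtol=1e-12)

    def test_three_level_weights_centre_on_one(self, medium_pp):
        ws = dose_exposure_weights(medium_pp)
        assert ws.frame["sw"].mean() == pytest.approx(1.0, abs=0.05)
        assert set(ws.frame["dose_level"].unique()) == {0, 1, 2, 3}


class TestDiagnostics:
    def test_unit_weights_zero_logs(self):
        frame = pd.DataFrame({"person_id": [0, 1], "k": [0, 0],
                              "sw": [1.0, 1.0], "w": [1.0, 1.0]})
        d = weight_diagnostics(WeightSet(frame=frame))
        assert d.loc[0, "mean_log_sw"] == 0.0
        assert d.loc[0, "sd_log_sw"] == 0.0

    def test_hand_computed_moments(self):
        e = np.e
        frame = pd.DataFrame({"person_id": [0, 1, 2], "k": [0, 0, 1],
                              "sw": [e, e, e**2], "w": [e, e**3, 1.0]})
        d = weight_diagnostics(WeightSet(frame=frame))
        assert d.loc[0, "mean_log_sw"] == pytest.approx(1.0)
        assert d.loc[0, "sd_log_sw"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc[0, "mean_log_w"] == pytest.approx(2.0)
        assert d.loc[0, "sd_log_w"] == pytest.approx(np.sqrt(2.0))
        assert d.loc[1, "mean_log_sw"] == pytest.approx(2.0)

    def test_nonpositive_weights_rejected(self):
        frame = pd.DataFrame({"person_id": [0], "k": [0], "sw": [0.0],
                              "w": [1.0]})
        with pytest.raises(ValueError):
            weight_diagnostics(WeightSet(frame=frame))
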