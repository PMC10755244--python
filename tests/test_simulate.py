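"""Generator determinism, parameter validation, causal-structure checks and
the counterfactual oracle."""

import numpy as np
import pandas as pd
import pytest

from msmcvd import (SimParams, counterfactual_truth, generate_cohort,
                    simulate_person_periods)
from msmcvd.simulate import (COMORBIDITY_CLASSES, EstimationError,
                             ParameterError, _EVENT_AGE_SLOPE,
                             _EVENT_FEMALE, _sigmoid, _stream)
from dataclasses import replace


class TestDeterminism:
    def test_same_seed_identical_tables(self, small_params):
        a = generate_cohort(small_params)
        b = generate_cohort(small_params)
        for name, tbl in a.tables().items():
            pd.testing.assert_frame_equal(tbl, b.tables()[name])

    def test_same_seed_identical_person_periods(self, small_params):
        pd.testing.assert_frame_equal(
            simulate_person_periods(small_params),
            simulate_person_periods(small_params),
        )

    def test_different_seed_differs(self, small_params):
        other = replace(small_params, seed=small_params.seed + 1)
        a = simulate_person_periods(small_params)
        b = simulate_person_periods(other)
        assert not a["A"].equals(b["A"])


class TestParameterValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            {"n_intervals": 0},
            {"female_frac": 1.5},
            {"severity_autocorr": 1.0},
            {"censor_rate": -0.1},
            {"baseline_age_sd": -1.0},
            {"baseline_event_logit": float("nan")},
            {"baseline_event_logit": -1.0},  # breaks rare-outcome regime
            {"comorbidity_emission_probs": {"psychotic": 0.5}},
        ],
    )
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ParameterError):
            SimParams(**bad)

    def test_rare_outcome_regime_holds_at_defaults(self, medium_pp):
        assert medium_pp["Y"].mean() < 0.1


class TestCausalStructure:
    def test_no_confounding_limit_flags_independent_of_treatment(self):
        """With severity channels to treatment switched off, comorbidity and
        treatment are associated only at Monte-Carlo noise level."""
        p = SimParams(n_persons=20000, n_intervals=6,
                      severity_effect_on_treatment=0.0,
                      treatment_effect_on_severity=0.0, seed=55)
        pp = simulate_person_periods(p)
        burden = sum(pp[f"com_{c}"] for c in COMORBIDITY_CLASSES)
        n = len(pp)
        # log-odds-ratio of treatment by any-comorbidity, with its SE
        t = pd.crosstab(burden > 0, pp["A"]).to_numpy().astype(float)
        log_or = np.log(t[1, 1] * t[0, 0] / (t[1, 0] * t[0, 1]))
        se = np.sqrt((1.0 / t).sum())
        assert abs(log_or) < 2 * se

    def test_confounding_is_material_in_crude_contrast(self):
        """At the default confounded settings the crude exposed/unexposed
        odds ratio is far from the conditional causal effect 1.34."""
        p = SimParams(n_persons=50000, seed=19)
        pp = simulate_person_periods(p)
        t = pd.crosstab(pp["A"], pp["Y"]).to_numpy().astype(float)
        crude_or = t[1, 1] * t[0, 0] / (t[1, 0] * t[0, 1])
        se = np.sqrt((1.0 / t).sum())
        assert abs(np.log(crude_or) - np.log(1.34)) > 2 * se

    def test_event_rows_terminate_follow_up(self, medium_pp):
        last = medium_pp.groupby("person_id").tail(1).set_index("person_id")
        with_event = medium_pp[medium_pp["Y"] == 1]
        assert with_event.groupby("person_id").size().max() == 1
        # the event row is always the person's last
        joined = with_event.set_index("person_id")["k"]
        assert (joined == last.loc[joined.index, "k"]).all()


class TestCounterfactualTruth:
    def test_null_when_no_direct_effect_and_no_feedback(self):
        p = SimParams(n_persons=1000, causal_log_hr=0.0,
                      treatment_effect_on_severity=0.0, seed=7)
        oracle = counterfactual_truth(p, mc_n=150_000)
        assert abs(np.log(oracle.hr_always_vs_never)) < 2 * oracle.mc_se

    def test_collapsible_limit_recovers_hr_two(self):
        """With the severity channel to events off, the conditional and
        marginal effects coincide: HR(always/never) = 2."""
        p = SimParams(n_persons=1000, causal_log_hr=np.log(2.0),
                      severity_effect_on_event=0.0, seed=7)
        oracle = counterfactual_truth(p, mc_n=150_000)
        assert abs(np.log(oracle.hr_always_vs_never) - np.log(2.0)) \
            < 2 * oracle.mc_se

    def test_matches_independent_brute_force_simulation(self):
        """A separately coded regime simulation (different seeds, independent
        draws per regime) agrees with the oracle within Monte-Carlo error."""
        p = SimParams(n_persons=1000, seed=33)
        oracle = counterfactual_truth(p, mc_n=120_000)
        brute = _brute_force_regime_hr(p, n=120_000, seed=987_654)
        assert abs(np.log(oracle.hr_always_vs_never) - np.log(brute["hr"])) \
            < 2 * np.hypot(oracle.mc_se, brute["se"])

    def test_stable_under_doubling_mc_n(self):
        p = SimParams(n_persons=1000, seed=3)
        a = counterfactual_truth(p, mc_n=100_000)
        b = counterfactual_truth(p, mc_n=200_000)
        assert abs(np.log(a.hr_always_vs_never) - np.log(b.hr_always_vs_never)) \
            < 3 * a.mc_se

    def test_mc_n_floor_enforced(self):
        with pytest.raises(ParameterError):
            counterfactual_truth(SimParams(n_persons=100), mc_n=500)

    def test_degenerate_no_events_raises(self):
        p = SimParams(n_persons=1000, n_intervals=1,
                      baseline_event_logit=-30.0, seed=1)
        with pytest.raises(EstimationError):
            counterfactual_truth(p, mc_n=10_000)


def _brute_force_regime_hr(params: SimParams, n: int, seed: int) -> dict:
    """Second implementation of the always/never contrast.

    Coded independently of the panel machinery: each regime is simulated on
    its own RNG (independent draws, so the binomial SE is exact rather than
    conservative), with a person-major state update per interval.
    """
    from msmcvd.simulate import (_COMORBIDITY_SLOPE, _EVENT_BURDEN_FRAC,
                                 _HOSP_BASE, _HOSP_SLOPE)

    rho = params.severity_autocorr
    innov = np.sqrt(1 - rho**2)
    base_logits = np.array(
        [np.log(q / (1 - q))
         for q in params.comorbidity_emission_probs.values()]
        + [np.log(_HOSP_BASE / (1 - _HOSP_BASE))]
    )
    slopes = np.array([_COMORBIDITY_SLOPE] * 5 + [_HOSP_SLOPE])

    counts = {}
    for regime, sub_seed in ((1, seed), (0, seed + 1)):
        rng = np.random.default_rng(sub_seed)
        female = rng.random(n) < params.female_frac
        age = np.clip(rng.normal(params.baseline_age_mean,
                                 params.baseline_age_sd, n), 19, 90)
        s = rng.normal(size=n)
        alive = np.ones(n, dtype=bool)
        ev = pt = 0
        for k in range(params.n_intervals):
            if k:
                s = rho * s + innov * rng.normal(size=n)
            a_prev = regime if k > 0 else 0
            e = s + params.treatment_effect_on_severity * a_prev
            burden = (
                rng.random((n, 6)) < _sigmoid(base_logits + slopes * e[:, None])
            ).sum(axis=1)
            logit_y = (params.baseline_event_logit
                       + params.causal_log_hr * regime
                       + params.severity_effect_on_event
                       * (s + _EVENT_BURDEN_FRAC * burden)
                       + _EVENT_AGE_SLOPE * (age - 40.0)
                       + _EVENT_FEMALE * female)
            y = alive & (rng.random(n) < _sigmoid(logit_y))
            ev += int(y.sum())
            pt += int(alive.sum())
            alive &= ~y
        counts[regime] = (ev, pt)
    (e1, n1), (e0, n0) = counts[1], counts[0]
    h1, h0 = e1 / n1, e0 / n0
    hr = (h1 / (1 - h1)) / (h0 / (1 - h0))
    se = np.sqrt(1 / e1 + 1 / (n1 - e1) + 1 / e0 + 1 / (n0 - e0))
    return {"hr": hr, "se": se}
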