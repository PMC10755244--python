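"""Fit the IPT-weighted marginal structural model and its conventional
comparators on one simulated cohort, against the counterfactual truth.

Prior treatment inflates the documented comorbidity record, which both
confounds later treatment and carries part of the treatment effect on
events — the classic situation in which regression adjustment fails but
inverse-probability weighting does not.
"""

import numpy as np

from msmcvd import (SimParams, compute_weights, counterfactual_truth,
                    fit_msm, fit_naive_time_varying, fit_treatment_models,
                    simulate_person_periods, standardized_regime_hr)

params = SimParams(n_persons=30000, n_intervals=12, seed=5)
pp = simulate_person_periods(params)

oracle = counterfactual_truth(params, mc_n=400_000)
print(f"counterfactual truth (always vs never treated): "
      f"HR = {oracle.hr_always_vs_never:.3f} "
      f"(MC band +-{2 * oracle.mc_se:.3f} on the log scale)")

models = fit_treatment_models(pp)
weights = compute_weights(pp, models)
print(f"stabilized weights: mean {weights.frame['sw'].mean():.3f}, "
      f"sd {weights.frame['sw'].std():.3f}")

msm = fit_msm(pp, weights=weights, exposure_cols=("A", "A_prev"))
naive = fit_naive_time_varying(pp)
crude = fit_msm(pp, weights=None, baseline_covariates=())

print(f"\ncrude pooled HR (no adjustment):        "
      f"{np.exp(crude.coefficients['A']):.3f}")
print(f"covariate-adjusted time-varying model:  "
      f"{standardized_regime_hr(naive, pp):.3f}  <- biased toward null")
print(f"IPT-weighted MSM:                       "
      f"{standardized_regime_hr(msm, pp):.3f}  <- recovers the truth")
hr = msm.hazard_ratios().loc["A"]
print(f"\ncurrent-exposure HR {hr['hr']:.3f} "
      f"(95% CI {hr['ci_low']:.3f}-{hr['ci_high']:.3f}, "
      "person-clustered sandwich)")
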