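"""Simulation-based validation studies for the MSM pipeline.

These helpers run the replicate experiments that back the package's claims:
stabilized-weight calibration (mean stabilized weight 1 per interval under a
correctly specified treatment model), recovery of the counterfactual
always- vs never-treated hazard ratio under treatment-confounder feedback
(where the conventional time-varying regression is biased), and confidence
interval coverage under the causal null.  All estimates use the same
public API the pipeline uses; nothing here is stubbed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .iptw import TreatmentModelSpec, compute_weights, fit_treatment_models
from .msm import fit_msm, fit_naive_time_varying, standardized_regime_hr
from .simulate import SimParams, counterfactual_truth, simulate_person_periods

__all__ = [
    "weight_calibration",
    "ReplicateStudy",
    "recovery_study",
    "null_coverage_study",
]

_SEED_CAP = 2**31 - 1


def _child_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(int(seed) & _SEED_CAP)
    return rng.integers(0, _SEED_CAP, size=n)


def weight_calibration(params: SimParams | None = None,
                       spec: TreatmentModelSpec | None = None) -> pd.DataFrame:
    """Per-interval mean stabilized weight with its standard error.

    Under a correctly specified denominator model E[sw_k] = 1 at every
    interval; the returned frame carries ``mean_sw``, ``se``, and the
    z-score of the departure from 1.
    """
    params = params or SimParams()
    spec = spec or TreatmentModelSpec()
    pp = simulate_person_periods(params)
    models = fit_treatment_models(pp, spec)
    ws = compute_weights(pp, models)
    g = ws.frame.groupby("k")["sw"]
    out = pd.DataFrame(
        {
            "mean_sw": g.mean(),
            "se": g.std(ddof=1) / np.sqrt(g.size()),
            "n": g.size(),
        }
    )
    out["z"] = (out["mean_sw"] - 1.0) / out["se"]
    return out


@dataclass
class ReplicateStudy:
    """Summary of a replicate simulation experiment."""

    oracle_hr: float
    oracle_mc_se: float
    msm_log_hr: np.ndarray
    naive_log_hr: np.ndarray
    msm_ci_covers: np.ndarray
    n_replicates: int

    @property
    def msm_bias(self) -> float:
        return float(np.mean(self.msm_log_hr) - np.log(self.oracle_hr))

    @property
    def naive_bias(self) -> float:
        # the comparator may be fitted on a leading subset of replicates
        return float(np.nanmean(self.naive_log_hr) - np.log(self.oracle_hr))

    @property
    def msm_bias_mc_se(self) -> float:
        return float(np.std(self.msm_log_hr, ddof=1) / np.sqrt(self.n_replicates))

    @property
    def coverage(self) -> float:
        return float(np.mean(self.msm_ci_covers))


def _one_replicate(params: SimParams, spec: TreatmentModelSpec,
                   fit_naive: bool):
    pp = simulate_person_periods(params)
    models = fit_treatment_models(pp, spec)
    ws = compute_weights(pp, models)
    msm = fit_msm(pp, weights=ws, exposure_cols=("A", "A_prev"))
    log_hr = float(np.log(standardized_regime_hr(msm, pp)))
    hr_row = msm.hazard_ratios().iloc[0]
    covers = bool(hr_row["ci_low"] <= 1.0 <= hr_row["ci_high"])
    naive_log_hr = np.nan
    if fit_naive:
        naive = fit_naive_time_varying(pp)
        naive_log_hr = float(np.log(standardized_regime_hr(naive, pp)))
    return log_hr, naive_log_hr, covers


def _replicate_study(params: SimParams, n_replicates: int, seed: int,
                     n_naive: int, mc_n: int) -> ReplicateStudy:
    oracle = counterfactual_truth(params, mc_n=mc_n)
    seeds = _child_seeds(seed, n_replicates)
    spec = TreatmentModelSpec()
    msm_est, naive_est, covers = [], [], []
    for i, s in enumerate(seeds):
        p = replace(params, seed=int(s))
        m, nv, c = _one_replicate(p, spec, fit_naive=i < n_naive)
        msm_est.append(m)
        naive_est.append(nv)
        covers.append(c)
    return ReplicateStudy(
        oracle_hr=oracle.hr_always_vs_never,
        oracle_mc_se=oracle.mc_se,
        msm_log_hr=np.array(msm_est),
        naive_log_hr=np.array(naive_est),
        msm_ci_covers=np.array(covers),
        n_replicates=n_replicates,
    )


def recovery_study(params: SimParams | None = None,
                   n_replicates: int = 1000, seed: int = 7,
                   n_naive: int = 200, mc_n: int = 1_000_000
                   ) -> ReplicateStudy:
    """Parameter recovery under treatment-confounder feedback.

    Repeatedly simulates cohorts, estimates the always- vs never-treated
    hazard ratio by the IPT-weighted MSM and by the unweighted time-varying
    comparator, and compares both with the Monte-Carlo oracle.

    A single cohort's estimate carries Monte-Carlo noise of about 0.18 on
    the log-HR scale at the default study size, so the bias of the MSM is
    averaged over many replicates (SE ~ 0.006 at 1000); the comparator's
    bias is an order of magnitude larger and is measured on the leading
    ``n_naive`` replicates.
    """
    params = params or SimParams()
    return _replicate_study(params, n_replicates, seed, n_naive=n_naive,
                            mc_n=mc_n)


def null_coverage_study(params: SimParams | None = None,
                        n_replicates: int = 200, seed: int = 11,
                        mc_n: int = 100_000) -> ReplicateStudy:
    """95% CI coverage of HR = 1 when the causal effect is switched off.

    Coverage is assessed on the current-exposure coefficient, whose true
    hazard ratio is 1 under ``causal_log_hr = 0`` (the sustained-regime
    contrast retains the pathway mediated by the documented comorbidity
    record, so it is not null)."""
    base = params or SimParams()
    null_params = replace(base, causal_log_hr=0.0)
    return _replicate_study(null_params, n_replicates, seed, n_naive=0,
                            mc_n=mc_n)
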