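"""Sensitivity analyses: e-values, weight-truncation sweep, comorbidity
exclusions.

The e-value is the minimum strength of association, on the risk-ratio
scale, that an unmeasured confounder would need with both exposure and
outcome to fully explain away an observed association:

    E = RR + sqrt(RR * (RR - 1))        for RR >= 1,

with RR < 1 first inverted to 1/RR.  Hazard ratios are accepted as risk
ratios under outcome rarity.  Because published reports mix two
conventions, results carry both the point-estimate e-value and the e-value
of the confidence limit closer to the null (1 when the CI crosses 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .iptw import WeightSet, truncate_weights
from .msm import MSMFit, fit_msm

__all__ = [
    "EValueResult",
    "evalue",
    "reported_evalue",
    "evalue_ci",
    "truncation_sweep",
    "comorbidity_exclusion_reanalysis",
    "DEFAULT_TRUNCATION_PAIRS",
]

DEFAULT_TRUNCATION_PAIRS = ((0, 100), (1, 99), (5, 95), (10, 90))


def evalue(rr: float) -> float:
    """E-value of a risk (or rare-outcome hazard) ratio, full precision."""
    if not np.isfinite(rr) or rr <= 0:
        raise ValueError(f"risk ratio must be positive, got {rr!r}")
    if rr < 1:
        rr = 1.0 / rr
    return float(rr + np.sqrt(rr * (rr - 1.0)))


def _round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal(10) ** -ndigits,
                                                  rounding=ROUND_HALF_UP))


def reported_evalue(rr: float, ndigits: int = 2) -> float:
    """E-value rounded half-up to the conventional 2-decimal reporting."""
    return _round_half_up(evalue(rr), ndigits)


@dataclass(frozen=True)
class EValueResult:
    """Point and CI-limit e-values for one hazard-ratio estimate."""

    rr_point: float
    rr_ci_lower: float
    rr_ci_upper: float
    evalue_point: float
    evalue_ci: float

    def rounded(self, ndigits: int = 2) -> "EValueResult":
        return EValueResult(
            self.rr_point, self.rr_ci_lower, self.rr_ci_upper,
            _round_half_up(self.evalue_point, ndigits),
            _round_half_up(self.evalue_ci, ndigits),
        )


def evalue_ci(point: float, lo: float, hi: float) -> EValueResult:
    """E-values for a point estimate and its 95% CI.

    The CI e-value uses the limit nearer the null (lo when point > 1, hi
    when point < 1) and equals 1 when the interval contains 1.
    """
    if not (lo <= point <= hi):
        raise ValueError(f"need lo <= point <= hi, got ({lo}, {point}, {hi})")
    e_point = evalue(point)
    if lo <= 1.0 <= hi:
        e_ci = 1.0
    elif point >= 1.0:
        e_ci = evalue(lo)
    else:
        e_ci = evalue(hi)
    return EValueResult(point, lo, hi, e_point, e_ci)


def truncation_sweep(person_periods: pd.DataFrame, weights: WeightSet,
                     pairs: tuple = DEFAULT_TRUNCATION_PAIRS,
                     **fit_kwargs) -> pd.DataFrame:
    """Refit the MSM under progressively truncated stabilized weights.

    The (0, 100) pair is the untruncated reference and reproduces the main
    fit exactly.  Returns one row per pair with the exposure HR and CI.
    """
    rows = []
    for lo, hi in pairs:
        ws = weights if (lo, hi) == (0, 100) else truncate_weights(weights, lo, hi)
        try:
            fit = fit_msm(person_periods, weights=ws, **fit_kwargs)
        except Exception as err:
            raise RuntimeError(
                f"MSM refit failed for truncation pair ({lo}, {hi})"
            ) from err
        hr = fit.hazard_ratios().iloc[0]
        rows.append(
            {
                "lower_pct": lo, "upper_pct": hi,
                "hr": hr["hr"], "ci_low": hr["ci_low"],
                "ci_high": hr["ci_high"], "n_events": fit.n_events,
            }
        )
    return pd.DataFrame(rows)


def comorbidity_exclusion_reanalysis(
    raw, comorbidity_groups: dict[str, tuple],
    analysis, index_code: str = "F43.1",
) -> pd.DataFrame:
    """Re-run the full analysis excluding persons ever carrying each group.

    ``comorbidity_groups`` maps a label to ICD-10 prefixes; persons with any
    matching claim (ignoring the cohort-defining index code itself, which
    every participant carries) are dropped and ``analysis(raw_subset)`` — a
    callable returning an :class:`MSMFit` — is re-run on the remainder.
    """
    rows = []
    codes = raw.claims["icd10_code"].astype(str)
    for label, prefixes in comorbidity_groups.items():
        m = pd.Series(False, index=raw.claims.index)
        for p in prefixes:
            m |= codes.str.startswith(p)
        m &= codes != index_code
        drop = set(raw.claims.loc[m, "person_id"])
        keep_mask = ~raw.persons["person_id"].isin(drop)
        if not keep_mask.any():
            raise RuntimeError(f"excluding group {label!r} empties the cohort")
        sub = type(raw)(
            persons=raw.persons[keep_mask].reset_index(drop=True),
            claims=raw.claims[~raw.claims["person_id"].isin(drop)].reset_index(drop=True),
            prescriptions=raw.prescriptions[
                ~raw.prescriptions["person_id"].isin(drop)
            ].reset_index(drop=True),
            checkups=raw.checkups[
                ~raw.checkups["person_id"].isin(drop)
            ].reset_index(drop=True),
            deaths=raw.deaths[~raw.deaths["person_id"].isin(drop)].reset_index(drop=True),
        )
        fit: MSMFit = analysis(sub)
        hr = fit.hazard_ratios().iloc[0]
        rows.append(
            {
                "excluded_group": label,
                "n_excluded": len(drop),
                "n_persons": fit.n_persons,
                "hr": hr["hr"],
                "ci_low": hr["ci_low"],
                "ci_high": hr["ci_high"],
                "n_events": fit.n_events,
            }
        )
    return pd.DataFrame(rows)
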