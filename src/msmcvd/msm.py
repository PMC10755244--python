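"""Marginal structural discrete-time survival model and comparators.

The MSM is a pooled logistic regression of the interval event indicator on
the exposure specification, baseline adjustment covariates and a flexible
time term, with observations weighted by stabilized IPT weights and
variance from the person-clustered sandwich estimator.  In the enforced
rare-outcome regime the exponentiated exposure coefficient approximates a
hazard ratio.  Comparators are the conventional time-fixed Cox model
(ever/never exposure, baseline covariates) and the time-varying Cox model
(counting-process layout, time-varying exposure and covariates), both known
to be biased under treatment-confounder feedback.

Exposure specifications: current-interval indicator ``A`` (main analysis),
per-class indicators, log-transformed cumulative DDD (dose–response), or a
degree-5 truncated-power spline of log cumulative DDD with knots at the
{5, 25, 50, 75, 95} percentiles of cumulative DDD among exposed
person-periods (nonlinearity check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import ConvergenceError, LogitFit, fit_weighted_logit
from .iptw import WeightSet, build_design

__all__ = [
    "MSMFit",
    "CoxFit",
    "SplineSpec",
    "EstimationError",
    "fit_msm",
    "fit_naive_time_varying",
    "standardized_regime_hr",
    "fit_cox_time_fixed",
    "fit_cox_time_varying",
    "spline_dose_response",
]

INTERVAL_DAYS = 91

Z975 = 1.959963984540054


class EstimationError(RuntimeError):
    """The requested fit is undefined on these data (e.g. no events)."""


DEFAULT_BASELINE = ("female", "age_at_index")


@dataclass
class MSMFit:
    """A fitted (weighted) pooled logistic hazard model."""

    label: str
    exposure_cols: tuple
    fit: LogitFit
    baseline_covariates: tuple
    extra_covariates: tuple
    interval_levels: tuple
    interval_as_categorical: bool
    n_persons: int
    n_events: int
    weighted: bool

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.fit.params, index=self.fit.names)

    @property
    def covariance(self) -> pd.DataFrame:
        return pd.DataFrame(self.fit.cov, index=self.fit.names,
                            columns=self.fit.names)

    def hazard_ratios(self) -> pd.DataFrame:
        """HR = exp(coef) with cluster-robust 95% Wald CIs, exposure terms."""
        sf = self.fit.summary_frame()
        rows = sf.loc[list(self.exposure_cols)]
        return pd.DataFrame(
            {
                "hr": np.exp(rows["coef"]),
                "ci_low": np.exp(rows["ci_low"]),
                "ci_high": np.exp(rows["ci_high"]),
                "log_hr": rows["coef"],
                "se_log_hr": rows["se"],
            }
        )

    def _design(self, df: pd.DataFrame):
        covs = tuple(self.exposure_cols) + tuple(self.baseline_covariates) \
            + tuple(self.extra_covariates)
        X, names = build_design(df, covs, self.interval_levels,
                                self.interval_as_categorical)
        return X, names

    def predict_hazard(self, df: pd.DataFrame) -> np.ndarray:
        X, _ = self._design(df)
        return self.fit.predict(X)


def _resolve_weights(weights, n: int) -> tuple[np.ndarray, bool]:
    if weights is None:
        return np.ones(n), False
    if isinstance(weights, WeightSet):
        arr = weights.sw
    else:
        arr = np.asarray(weights, dtype=float)
    if len(arr) != n:
        raise ValueError(f"weights length {len(arr)} != rows {n}")
    return arr, True


def fit_msm(person_periods: pd.DataFrame,
            weights: WeightSet | np.ndarray | None = None,
            exposure_cols: tuple = ("A",),
            baseline_covariates: tuple = DEFAULT_BASELINE,
            extra_covariates: tuple = (),
            interval_as_categorical: bool = True,
            label: str = "msm",
            min_events: int = 10) -> MSMFit:
    """Weighted pooled logistic regression of Y on exposure, V and time.

    ``weights`` may be a :class:`WeightSet` (its stabilized column is used),
    a bare array aligned to the rows, or None for an unweighted fit.  The
    covariance is always the person-clustered sandwich.
    """
    pp = person_periods.sort_values(["person_id", "k"], kind="mergesort")
    n_events = int(pp["Y"].sum())
    if n_events == 0:
        raise EstimationError("zero events; hazard model undefined")
    if n_events < min_events:
        raise EstimationError(
            f"only {n_events} events (< {min_events}); estimates unstable"
        )
    if isinstance(weights, WeightSet):
        key = pd.MultiIndex.from_frame(pp[["person_id", "k"]])
        wkey = pd.MultiIndex.from_frame(weights.frame[["person_id", "k"]])
        aligned = pd.Series(weights.frame["sw"].to_numpy(), index=wkey)
        w = aligned.reindex(key).to_numpy()
        if np.isnan(w).any():
            raise ValueError("weights do not cover all person-period rows")
        weighted = True
    else:
        w, weighted = _resolve_weights(weights, len(pp))
    levels = tuple(sorted(pp["k"].unique()))
    covs = tuple(exposure_cols) + tuple(baseline_covariates) + tuple(extra_covariates)
    X, names = build_design(pp, covs, levels, interval_as_categorical)
    try:
        fit = fit_weighted_logit(
            X, pp["Y"].to_numpy(dtype=float), weights=w,
            clusters=pp["person_id"].to_numpy(), names=names,
        )
    except ConvergenceError as err:
        raise EstimationError(
            f"hazard model failed to converge: {err}"
        ) from err
    return MSMFit(
        label=label,
        exposure_cols=tuple(exposure_cols),
        fit=fit,
        baseline_covariates=tuple(baseline_covariates),
        extra_covariates=tuple(extra_covariates),
        interval_levels=levels,
        interval_as_categorical=interval_as_categorical,
        n_persons=int(pp["person_id"].nunique()),
        n_events=n_events,
        weighted=weighted,
    )


def fit_naive_time_varying(person_periods: pd.DataFrame,
                           exposure_cols: tuple = ("A",),
                           baseline_covariates: tuple = DEFAULT_BASELINE,
                           time_varying_covariates: tuple = (
                               "com_psychotic", "com_bipolar", "com_depressive",
                               "com_anxiety", "com_somatoform", "psych_hosp",
                           ),
                           label: str = "time_varying_pooled_logistic") -> MSMFit:
    """Unweighted discrete-time comparator adjusting for current L_k.

    This is the conventional time-varying regression adjustment that is
    biased under treatment-confounder feedback.
    """
    return fit_msm(
        person_periods, weights=None, exposure_cols=exposure_cols,
        baseline_covariates=baseline_covariates,
        extra_covariates=tuple(time_varying_covariates), label=label,
    )


# history encodings and their values under the sustained regimes: at k = 0
# nobody has prior treatment even under "always"
_HISTORY_REGIME = {
    "A_prev": lambda k, treated: (k > 0).astype(int) if treated else 0,
    "ever_treated_prev": lambda k, treated: (k > 0).astype(int) if treated else 0,
}


def _pin_regime(df: pd.DataFrame, cols, treated: bool) -> pd.DataFrame:
    out = df.copy()
    k = df["k"].to_numpy()
    for c in cols:
        if c in _HISTORY_REGIME:
            out[c] = _HISTORY_REGIME[c](k, treated)
        else:
            out[c] = int(treated)
    return out


def standardized_regime_hr(msm_fit: MSMFit,
                           person_periods: pd.DataFrame) -> float:
    """Model-implied always- vs never-treated pooled hazard ratio.

    Predicted interval hazards are computed for every observed person-period
    row with the exposure (and any treatment-history terms in the model)
    pinned to the sustained-treatment and never-treatment regimes, then
    pooled into a discrete-time odds ratio — the same functional the
    counterfactual oracle reports.
    """
    pp = person_periods.sort_values(["person_id", "k"], kind="mergesort")
    h1 = float(np.mean(msm_fit.predict_hazard(
        _pin_regime(pp, msm_fit.exposure_cols, True))))
    h0 = float(np.mean(msm_fit.predict_hazard(
        _pin_regime(pp, msm_fit.exposure_cols, False))))
    return (h1 / (1 - h1)) / (h0 / (1 - h0))


@dataclass
class CoxFit:
    """A conventional Cox comparator fit (lifelines behind the scenes)."""

    label: str
    exposure_cols: tuple
    summary: pd.DataFrame
    n_persons: int
    n_events: int
    model: object = field(repr=False, default=None)

    def hazard_ratios(self) -> pd.DataFrame:
        rows = self.summary.loc[list(self.exposure_cols)]
        return pd.DataFrame(
            {
                "hr": np.exp(rows["coef"]),
                "ci_low": np.exp(rows["coef"] - Z975 * rows["se(coef)"]),
                "ci_high": np.exp(rows["coef"] + Z975 * rows["se(coef)"]),
                "log_hr": rows["coef"],
                "se_log_hr": rows["se(coef)"],
            }
        )


def fit_cox_time_fixed(person_table: pd.DataFrame,
                       exposure_col: str = "ever_exposed",
                       covariates: tuple = DEFAULT_BASELINE,
                       duration_col: str = "duration_days",
                       event_col: str = "event") -> CoxFit:
    """Time-fixed Cox proportional hazards fit (Efron ties)."""
    from lifelines import CoxPHFitter

    df = person_table[[duration_col, event_col, exposure_col, *covariates]].copy()
    if df[event_col].sum() == 0:
        raise EstimationError("no events; Cox model undefined")
    if df[exposure_col].nunique() < 2:
        raise EstimationError(f"exposure {exposure_col!r} is constant")
    cph = CoxPHFitter()
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return CoxFit(
        label="cox_time_fixed",
        exposure_cols=(exposure_col,),
        summary=cph.summary,
        n_persons=len(df),
        n_events=int(df[event_col].sum()),
        model=cph,
    )


def fit_cox_time_varying(person_periods: pd.DataFrame,
                         exposure_cols: tuple = ("A",),
                         covariates: tuple = DEFAULT_BASELINE,
                         time_varying_covariates: tuple = ()) -> CoxFit:
    """Time-varying Cox fit on the counting-process (start, stop] layout."""
    from lifelines import CoxTimeVaryingFitter

    pp = person_periods.sort_values(["person_id", "k"], kind="mergesort").copy()
    if "interval_start" in pp.columns:
        start = pp["interval_start"].to_numpy(dtype=float)
        stop = pp["interval_end"].to_numpy(dtype=float)
    else:
        start = pp["k"].to_numpy(dtype=float) * INTERVAL_DAYS
        stop = start + INTERVAL_DAYS
    stop = np.maximum(stop, start + 0.5)  # guard zero-length final intervals
    overlap = pp.groupby("person_id")["k"].apply(
        lambda s: s.duplicated().any())
    if overlap.any():
        raise ValueError("overlapping intervals within person")
    if pp["Y"].sum() == 0:
        raise EstimationError("no events; Cox model undefined")
    df = pd.DataFrame(
        {
            "person_id": pp["person_id"].to_numpy(),
            "start": start,
            "stop": stop,
            "event": pp["Y"].to_numpy(),
        }
    )
    used = tuple(exposure_cols) + tuple(covariates) + tuple(time_varying_covariates)
    for c in used:
        df[c] = pp[c].to_numpy(dtype=float)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(df, id_col="person_id", start_col="start", stop_col="stop",
                event_col="event")
    return CoxFit(
        label="cox_time_varying",
        exposure_cols=tuple(exposure_cols),
        summary=ctv.summary,
        n_persons=int(pp["person_id"].nunique()),
        n_events=int(pp["Y"].sum()),
        model=ctv,
    )


@dataclass(frozen=True)
class SplineSpec:
    """Degree-5 truncated-power spline of log(1 + cumulative DDD)."""

    degree: int = 5
    knot_percentiles: tuple = (5, 25, 50, 75, 95)


def _spline_knots(cum_ddd: pd.Series, spec: SplineSpec,
                  x_max: float) -> np.ndarray:
    exposed = cum_ddd[cum_ddd > 0]
    if not len(exposed):
        raise EstimationError("no exposed person-periods; spline undefined")
    knots = np.log1p(np.percentile(exposed, spec.knot_percentiles))
    knots = np.unique(knots)
    knots = knots[(knots > 0) & (knots < x_max)]
    if len(knots) < len(spec.knot_percentiles):
        warnings.warn("duplicate or boundary spline knots merged",
                      stacklevel=2)
    return knots


def spline_basis(cum_ddd, knots: np.ndarray, degree: int,
                 x_max: float) -> pd.DataFrame:
    """Clamped B-spline basis of x = log1p(dose); zero row at dose 0.

    The full basis has (interior knots + degree + 1) members summing to 1;
    the first is dropped (absorbed by the model intercept), which also makes
    the basis vanish identically at dose 0, so fitted hazard ratios are
    relative to the unexposed reference by construction.
    """
    from scipy.interpolate import BSpline

    x = np.clip(np.log1p(np.asarray(cum_ddd, dtype=float)), 0.0, x_max)
    t = np.r_[np.zeros(degree + 1), knots, np.full(degree + 1, x_max)]
    M = BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()
    return pd.DataFrame(
        {f"dose_b{j}": M[:, j] for j in range(1, M.shape[1])}
    )


def spline_dose_response(person_periods: pd.DataFrame,
                         weights: WeightSet | np.ndarray | None,
                         spec: SplineSpec | None = None,
                         dose_col: str = "cum_ddd",
                         baseline_covariates: tuple = DEFAULT_BASELINE,
                         n_grid: int = 60):
    """Weighted spline hazard model; returns (MSMFit, HR-vs-dose curve).

    The curve frame gives the pointwise hazard ratio relative to dose zero
    with delta-method 95% CIs over a dose grid spanning the observed range.
    """
    spec = spec or SplineSpec()
    pp = person_periods.sort_values(["person_id", "k"], kind="mergesort").copy()
    if pp[dose_col].nunique() <= spec.degree + len(spec.knot_percentiles):
        raise EstimationError("fewer distinct dose values than basis dimension")
    scale = float(np.log1p(pp[dose_col].max()))
    knots = _spline_knots(pp[dose_col], spec, scale)
    basis = spline_basis(pp[dose_col], knots, spec.degree, scale)
    # normalize columns to unit maximum: basis members supported only in the
    # sparse dose tails otherwise have tiny scale and ill-conditioned fits
    col_scale = basis.max(axis=0).replace(0.0, 1.0)
    basis = basis / col_scale
    basis.index = pp.index
    aug = pd.concat([pp, basis], axis=1)
    exposure_cols = tuple(basis.columns)
    msm_fit = fit_msm(
        aug, weights=weights, exposure_cols=exposure_cols,
        baseline_covariates=baseline_covariates, label="spline_dose_response",
    )
    beta = msm_fit.coefficients[list(exposure_cols)].to_numpy()
    cov = msm_fit.covariance.loc[list(exposure_cols), list(exposure_cols)].to_numpy()
    grid = np.linspace(0.0, float(pp[dose_col].max()), n_grid)
    B = (spline_basis(grid, knots, spec.degree, scale) / col_scale).to_numpy()
    log_hr = B @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", B, cov, B))
    curve = pd.DataFrame(
        {
            "cum_ddd": grid,
            "hr": np.exp(log_hr),
            "ci_low": np.exp(log_hr - Z975 * se),
            "ci_high": np.exp(log_hr + Z975 * se),
        }
    )
    return msm_fit, curve
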