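"""Inverse-probability-of-treatment weights for the marginal structural model.

Treatment probabilities come from pooled logistic regressions over
person-periods with an interval term: the *denominator* model conditions on
baseline covariates V, treatment history and the time-varying covariate
block L_k; the *numerator* (stabilizing) model conditions on V and history
only.  For person i at interval k,

    w_i(k)  = prod_{j<=k} 1 / P(A_j = a_ij | history_j, L_j, V)
    sw_i(k) = prod_{j<=k} P(A_j = a_ij | history_j, V)
              / P(A_j = a_ij | history_j, L_j, V)

with products over at-risk intervals.  Correct specification of the
denominator makes the stabilized weights mean-one at every interval, the
standard calibration diagnostic.  Separate multinomial weights support the
dose–response analysis (interval dose discretized into zero plus tertiles
of positive dose).  Weight truncation at percentile pairs probes positivity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._glm import PROB_FLOOR, LogitFit, SeparationError, fit_weighted_logit

__all__ = [
    "TreatmentModelSpec",
    "FittedTreatmentModels",
    "WeightSet",
    "PositivityError",
    "fit_treatment_models",
    "compute_weights",
    "truncate_weights",
    "dose_exposure_weights",
    "weight_diagnostics",
]

log = logging.getLogger(__name__)

PositivityError = SeparationError

DEFAULT_TIME_VARYING = (
    "com_psychotic", "com_bipolar", "com_depressive", "com_anxiety",
    "com_somatoform", "psych_hosp",
)


@dataclass(frozen=True)
class TreatmentModelSpec:
    """Covariate layout of the numerator and denominator treatment models.

    The numerator covariates are the denominator's minus the time-varying
    block (enforced), so the stabilized weight cancels everything but the
    L_k contribution.
    """

    baseline_covariates: tuple = ("female", "age_at_index")
    time_varying_covariates: tuple = DEFAULT_TIME_VARYING
    history: tuple = ("A_prev", "ever_treated_prev")
    interval_as_categorical: bool = True
    exposure_col: str = "A"

    def __post_init__(self):
        overlap = set(self.baseline_covariates) & set(self.time_varying_covariates)
        if overlap:
            raise ValueError(
                f"covariates {sorted(overlap)} appear in both the baseline and "
                "time-varying blocks"
            )

    @property
    def numerator_covariates(self) -> tuple:
        return tuple(self.baseline_covariates) + tuple(self.history)

    @property
    def denominator_covariates(self) -> tuple:
        return self.numerator_covariates + tuple(self.time_varying_covariates)


def _interval_dummies(k: pd.Series, levels: tuple) -> tuple[np.ndarray, list[str]]:
    cols = [(k == lv).to_numpy(dtype=float) for lv in levels[1:]]  # first = ref
    names = [f"I(k={lv})" for lv in levels[1:]]
    if cols:
        return np.column_stack(cols), names
    return np.empty((len(k), 0)), names


def build_design(df: pd.DataFrame, covariates: tuple, interval_levels: tuple,
                 interval_as_categorical: bool = True):
    """Constant + covariate columns + interval term; returns (X, names)."""
    parts = [np.ones((len(df), 1))]
    names = ["const"]
    for c in covariates:
        parts.append(df[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    if interval_as_categorical:
        dum, dnames = _interval_dummies(df["k"], interval_levels)
        parts.append(dum)
        names.extend(dnames)
    else:
        parts.append(df["k"].to_numpy(dtype=float)[:, None])
        names.append("k")
    return np.hstack(parts), names


@dataclass
class FittedTreatmentModels:
    """Numerator and denominator treatment-probability models."""

    spec: TreatmentModelSpec
    numerator: LogitFit
    denominator: LogitFit
    interval_levels: tuple

    def _probs(self, df: pd.DataFrame, fit: LogitFit, covariates: tuple):
        X, _ = build_design(df, covariates, self.interval_levels,
                            self.spec.interval_as_categorical)
        return fit.predict(X)

    def prob_treated(self, df: pd.DataFrame, which: str = "denominator"):
        if which == "denominator":
            return self._probs(df, self.denominator, self.spec.denominator_covariates)
        return self._probs(df, self.numerator, self.spec.numerator_covariates)

    def prob_observed(self, df: pd.DataFrame, which: str = "denominator"):
        p = self.prob_treated(df, which)
        a = df[self.spec.exposure_col].to_numpy()
        return np.where(a == 1, p, 1.0 - p)


def fit_treatment_models(person_periods: pd.DataFrame,
                         spec: TreatmentModelSpec | None = None
                         ) -> FittedTreatmentModels:
    """Fit pooled-over-time numerator and denominator logistic models.

    Warns if some interval lacks both treated and untreated rows (positivity
    screen); raises :class:`PositivityError` if a fitted probability is
    numerically 0 or 1 (separation).
    """
    spec = spec or TreatmentModelSpec()
    df = person_periods
    a = df[spec.exposure_col]
    by_k = df.groupby("k")[spec.exposure_col].agg(["min", "max"])
    deg = by_k[(by_k["min"] == by_k["max"])]
    if len(deg):
        warnings.warn(
            f"intervals {list(deg.index)} have a single observed treatment "
            "level; positivity is suspect there",
            stacklevel=2,
        )
    levels = tuple(sorted(df["k"].unique()))
    Xd, dnames = build_design(df, spec.denominator_covariates, levels,
                              spec.interval_as_categorical)
    Xn, nnames = build_design(df, spec.numerator_covariates, levels,
                              spec.interval_as_categorical)
    y = a.to_numpy(dtype=float)
    den = fit_weighted_logit(Xd, y, names=dnames, check_separation=True)
    num = fit_weighted_logit(Xn, y, names=nnames, check_separation=True)
    return FittedTreatmentModels(spec=spec, numerator=num, denominator=den,
                                 interval_levels=levels)


@dataclass
class WeightSet:
    """Per person-period IPT weights plus truncation metadata."""

    frame: pd.DataFrame  # person_id, k, p_num_obs, p_den_obs, sw, w
    truncation: tuple | None = None
    n_clipped: int = 0
    kind: str = "binary"

    @property
    def sw(self) -> np.ndarray:
        return self.frame["sw"].to_numpy()

    @property
    def w(self) -> np.ndarray:
        return self.frame["w"].to_numpy()

    def diagnostics(self) -> pd.DataFrame:
        return weight_diagnostics(self)


def _cumprod_by_person(df: pd.DataFrame, col: str) -> np.ndarray:
    return df.groupby("person_id", sort=False)[col].cumprod().to_numpy()


def _weights_from_probs(pp: pd.DataFrame, p_num_obs, p_den_obs,
                        kind: str) -> WeightSet:
    clip_lo, clip_hi = PROB_FLOOR, 1.0 - PROB_FLOOR
    n_clipped = int(np.sum((p_den_obs < clip_lo) | (p_den_obs > clip_hi))
                    + np.sum((p_num_obs < clip_lo) | (p_num_obs > clip_hi)))
    if n_clipped:
        log.info("clipped %d fitted probabilities to [%.0e, 1-%.0e]",
                 n_clipped, clip_lo, clip_lo)
    p_num_obs = np.clip(p_num_obs, clip_lo, clip_hi)
    p_den_obs = np.clip(p_den_obs, clip_lo, clip_hi)
    frame = pp[["person_id", "k"]].copy()
    frame["p_num_obs"] = p_num_obs
    frame["p_den_obs"] = p_den_obs
    frame["_ratio"] = p_num_obs / p_den_obs
    frame["_inv"] = 1.0 / p_den_obs
    frame["sw"] = _cumprod_by_person(frame, "_ratio")
    frame["w"] = _cumprod_by_person(frame, "_inv")
    frame = frame.drop(columns=["_ratio", "_inv"])
    if not np.all(np.isfinite(frame["w"])):
        bad = frame.index[~np.isfinite(frame["w"])][0]
        raise FloatingPointError(f"weight underflow/overflow at row {bad}")
    return WeightSet(frame=frame, n_clipped=n_clipped, kind=kind)


def compute_weights(person_periods: pd.DataFrame,
                    models: FittedTreatmentModels,
                    stabilized: bool = True) -> WeightSet:
    """Cumulative-product IPT weights over each person's at-risk intervals.

    Both stabilized and non-stabilized weights are materialized (``sw`` and
    ``w`` columns); ``stabilized`` records which one downstream fits should
    use by default via :func:`WeightSet` consumers.
    """
    pp = person_periods.sort_values(["person_id", "k"], kind="mergesort")
    p_num = models.prob_observed(pp, "numerator")
    p_den = models.prob_observed(pp, "denominator")
    ws = _weights_from_probs(pp, p_num, p_den, kind="binary")
    if not stabilized:
        ws.frame["sw"] = ws.frame["w"]
    return ws


def truncate_weights(weights: WeightSet, lower_pct: float,
                     upper_pct: float) -> WeightSet:
    """Clamp weights to their [lower_pct, upper_pct] percentile band.

    Percentiles are computed over all person-period weights with linear
    interpolation, separately for sw and w.  (0, 100) is the identity.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    frame = weights.frame.copy()
    if not len(frame):
        raise ValueError("empty weight set")
    for col in ("sw", "w"):
        lo, hi = np.percentile(frame[col], [lower_pct, upper_pct])
        frame[col] = frame[col].clip(lo, hi)
    return replace(weights, frame=frame, truncation=(lower_pct, upper_pct))


def _dose_levels(interval_ddd: pd.Series, n_positive_levels: int = 3):
    """Discretize interval dose into 0 plus tertiles of positive dose."""
    pos = interval_ddd[interval_ddd > 0]
    if not len(pos):
        return np.zeros(len(interval_ddd), dtype=int), [0.0]
    qs = np.quantile(pos, np.linspace(0, 1, n_positive_levels + 1)[1:-1])
    cuts = np.unique(qs)
    levels = np.zeros(len(interval_ddd), dtype=int)
    mask = interval_ddd > 0
    levels[mask] = 1 + np.searchsorted(cuts, interval_ddd[mask], side="left")
    return levels, list(cuts)


def dose_exposure_weights(person_periods: pd.DataFrame,
                          spec: TreatmentModelSpec | None = None,
                          n_positive_levels: int = 3,
                          dose_col: str = "interval_ddd") -> WeightSet:
    """Stabilized IPT weights for the ordered dose-level exposure.

    Interval dose is discretized (0 + tertiles of positive dose); numerator
    and denominator multinomial logistic models give each row's probability
    of its observed level, and the weight is the cumulative product of
    observed-level probability ratios.  An empty level triggers a collapse
    warning and a refit on the reduced level set; a two-level collapse
    reduces exactly to :func:`compute_weights`.
    """
    import statsmodels.api as sm

    spec = spec or TreatmentModelSpec()
    pp = person_periods.sort_values(["person_id", "k"], kind="mergesort").copy()
    levels, cuts = _dose_levels(pp[dose_col], n_positive_levels)
    uniq = np.unique(levels)
    if len(uniq) < np.max(levels) + 1:
        warnings.warn(
            "empty dose level detected; collapsing to observed levels and "
            "refitting", stacklevel=2,
        )
        remap = {lv: i for i, lv in enumerate(uniq)}
        levels = np.vectorize(remap.get)(levels)
        uniq = np.unique(levels)
    pp["_dose_level"] = levels

    if len(uniq) == 1:
        frame = pp[["person_id", "k"]].copy()
        frame["p_num_obs"] = 1.0
        frame["p_den_obs"] = 1.0
        frame["sw"] = 1.0
        frame["w"] = 1.0
        return WeightSet(frame=frame, kind="dose")
    if len(uniq) == 2:
        binary = pp.copy()
        binary[spec.exposure_col] = (binary["_dose_level"] > 0).astype(int)
        models = fit_treatment_models(binary, spec)
        ws = compute_weights(binary, models)
        ws.kind = "dose"
        return ws

    k_levels = tuple(sorted(pp["k"].unique()))
    Xd, _ = build_design(pp, spec.denominator_covariates, k_levels,
                         spec.interval_as_categorical)
    Xn, _ = build_design(pp, spec.numerator_covariates, k_levels,
                         spec.interval_as_categorical)
    y = pp["_dose_level"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        den = sm.MNLogit(y, Xd).fit(method="newton", disp=0, maxiter=200)
        num = sm.MNLogit(y, Xn).fit(method="newton", disp=0, maxiter=200)
    p_den = den.predict(Xd)
    p_num = num.predict(Xn)
    rows = np.arange(len(pp))
    p_den_obs = np.asarray(p_den)[rows, y]
    p_num_obs = np.asarray(p_num)[rows, y]
    ws = _weights_from_probs(pp, p_num_obs, p_den_obs, kind="dose")
    ws.frame["dose_level"] = y
    return ws


def weight_diagnostics(weights: WeightSet) -> pd.DataFrame:
    """Per-interval mean and SD of log(sw) and log(w), with row counts."""
    frame = weights.frame
    if (frame[["sw", "w"]] <= 0).any().any():
        raise ValueError("weights must be positive")
    d = frame.assign(log_sw=np.log(frame["sw"]), log_w=np.log(frame["w"]))
    out = d.groupby("k").agg(
        mean_log_sw=("log_sw", "mean"),
        sd_log_sw=("log_sw", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        mean_log_w=("log_w", "mean"),
        sd_log_w=("log_w", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        mean_sw=("sw", "mean"),
        n=("sw", "size"),
    )
    return out
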