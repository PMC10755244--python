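"""Synthetic claims-style cohorts with treatment-confounder feedback.

The generator emulates an administrative-claims follow-up of adults indexed
at a first PTSD diagnosis: a latent cardiometabolic-psychiatric vulnerability
``S_k`` evolves as a stationary AR(1) process; the *expressed* symptom
severity ``E_k = S_k + tau * A_{k-1}`` additionally reflects prior
antidepressant treatment (symptom relief, or increased surveillance and
coding, depending on the sign of ``tau``).  Expressed severity drives the
emission of psychiatric comorbidity claims and psychiatric hospitalization;
prescribers respond to the documented comorbidity burden, so treatment
``A_k`` depends on the *observed* covariates (plus treatment persistence),
while the discrete-time event hazard depends on latent vulnerability and
current treatment:

    logit P(A_k = 1) = a0 + beta_T * burden_k + rho_A * A_{k-1} + ...
    logit P(Y_k = 1) = b0 + psi * A_k + beta_Y * (S_k + c * burden_k) + ...

where ``burden_k`` is the documented comorbidity burden (count of comorbidity
flags plus hospitalization).  This is the canonical feedback structure: the
comorbidity record is affected by prior treatment, confounds future
treatment (shared latent cause ``S``), and mediates part of the effect of
prior treatment on events.  Conventional regression adjustment for the
time-varying covariates therefore blocks a genuine indirect pathway and is
biased toward the null (for ``tau > 0``), while IPT weighting on the
documented covariates recovers the full contrast.  Because the hazard
depends on treatment history only through (A_k, A_{k-1}), a marginal
structural model with current and previous-interval exposure terms is
correctly specified.
The marginal always-treated vs never-treated hazard ratio is *not* equal to
``exp(psi)`` because the logistic hazard is non-collapsible over ``S``; it
is computed by Monte-Carlo regime simulation (:func:`counterfactual_truth`).

Calendar is abstract: integer days, index date at day 0, intervals of
exactly 91 days ("every 3 months").
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "COMORBIDITY_CLASSES",
    "COMORBIDITY_ICD10",
    "INTERVAL_DAYS",
    "SimParams",
    "RawRecords",
    "TruthOracle",
    "ParameterError",
    "EstimationError",
    "simulate_person_periods",
    "generate_cohort",
    "counterfactual_truth",
]

INTERVAL_DAYS = 91

COMORBIDITY_CLASSES = ("psychotic", "bipolar", "depressive", "anxiety", "somatoform")

# ICD-10 three-character groups defining each comorbidity class, and concrete
# codes the generator stamps on emitted claims.
COMORBIDITY_ICD10 = {
    "psychotic": ("F20", "F21", "F22", "F23", "F24", "F25", "F28", "F29"),
    "bipolar": ("F30", "F31"),
    "depressive": ("F32", "F33", "F34"),
    "anxiety": ("F40", "F41", "F42", "F43"),
    "somatoform": ("F45",),
}
_EMITTED_CODES = {
    "psychotic": ("F20.0", "F23.1", "F25.0"),
    "bipolar": ("F31.1", "F30.0"),
    "depressive": ("F32.1", "F33.1", "F34.1"),
    "anxiety": ("F41.0", "F41.1", "F40.0", "F42.2"),
    "somatoform": ("F45.0", "F45.2"),
}

PTSD_CODE = "F43.1"

# Fixed structural constants of the generating process (not exposed as
# parameters: they shape the measurement model, not the causal contrast).
_COMORBIDITY_SLOPE = 0.8        # expressed severity -> comorbidity log-odds
_HOSP_BASE = 0.01               # psychiatric-hospitalization prob at E = 0
_HOSP_SLOPE = 1.0
_TREAT_INTERCEPT = -3.4         # prescriber's base initiation log-odds
_TREAT_PERSISTENCE = 2.2        # log-odds bonus while already on treatment
_TREAT_FEMALE = 0.25
_EVENT_AGE_SLOPE = 0.04         # per year, centred at 40
_EVENT_FEMALE = -0.10
_EVENT_BURDEN_FRAC = 0.5        # documented burden counts this fraction of a
                                # latent-severity unit in the event model
_MACE_TYPE_PROBS = {            # composite split among the four components
    "CAD_revasc": 0.40,
    "ischaemic_stroke": 0.30,
    "haemorrhagic_stroke": 0.15,
    "cv_death": 0.15,
}
_DRUG_CLASS_PROBS = {"SSRI": 0.60, "SNRI": 0.15, "TCA": 0.20, "other": 0.05}

_ORIGIN_YEAR = 2004  # day 0 of the abstract calendar


class ParameterError(ValueError):
    """A simulation parameter is non-finite or out of range."""


class EstimationError(RuntimeError):
    """A Monte-Carlo or model-based estimate is undefined (e.g. no events)."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the claims-cohort generating process.

    Defaults are the package's reference study conditions: a predominantly
    female cohort indexed around age 40, roughly half ever-treated over
    three years of follow-up, a rare per-interval event probability, and a
    causal hazard ratio of 1.34 for current antidepressant exposure.
    """

    n_persons: int = 5000
    n_intervals: int = 12
    baseline_age_mean: float = 39.8
    baseline_age_sd: float = 12.6
    female_frac: float = 0.61
    severity_autocorr: float = 0.7
    treatment_effect_on_severity: float = 1.0
    severity_effect_on_treatment: float = 0.7
    causal_log_hr: float = float(np.log(1.34))
    severity_effect_on_event: float = 0.5
    baseline_event_logit: float = -5.2
    comorbidity_emission_probs: dict = field(
        default_factory=lambda: {
            "psychotic": 0.02,
            "bipolar": 0.04,
            "depressive": 0.22,
            "anxiety": 0.28,
            "somatoform": 0.10,
        }
    )
    censor_rate: float = 0.01
    seed: int = 20230

    def __post_init__(self):
        scalars = {
            "baseline_age_mean": self.baseline_age_mean,
            "baseline_age_sd": self.baseline_age_sd,
            "severity_autocorr": self.severity_autocorr,
            "treatment_effect_on_severity": self.treatment_effect_on_severity,
            "severity_effect_on_treatment": self.severity_effect_on_treatment,
            "causal_log_hr": self.causal_log_hr,
            "severity_effect_on_event": self.severity_effect_on_event,
            "baseline_event_logit": self.baseline_event_logit,
            "censor_rate": self.censor_rate,
            "female_frac": self.female_frac,
        }
        for name, v in scalars.items():
            _check(np.isfinite(v), f"{name} must be finite, got {v!r}")
        _check(self.n_persons >= 1, "n_persons must be >= 1")
        _check(self.n_intervals >= 1, "n_intervals must be >= 1")
        _check(0.0 <= self.female_frac <= 1.0, "female_frac must be in [0, 1]")
        _check(0.0 <= self.censor_rate <= 1.0, "censor_rate must be in [0, 1]")
        _check(
            0.0 <= self.severity_autocorr < 1.0,
            "severity_autocorr must be in [0, 1)",
        )
        _check(self.baseline_age_sd >= 0, "baseline_age_sd must be >= 0")
        _check(
            set(self.comorbidity_emission_probs) == set(COMORBIDITY_CLASSES),
            "comorbidity_emission_probs must map exactly the classes "
            f"{COMORBIDITY_CLASSES}",
        )
        for c, p in self.comorbidity_emission_probs.items():
            _check(0.0 < p < 1.0, f"emission probability for {c} must be in (0, 1)")
        # Rare-outcome regime: the per-interval hazard at the average profile
        # must stay below 0.1 under either sustained regime, so that
        # discrete-time odds ratios approximate hazard ratios.
        worst = _sigmoid(self.baseline_event_logit + max(self.causal_log_hr, 0.0))
        _check(
            worst < 0.1,
            "per-interval event probability at the mean profile exceeds 0.1; "
            "lower baseline_event_logit (rare-outcome regime required)",
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        return cls(**d)


@dataclass
class RawRecords:
    """Claims-style tables keyed by person and integer day."""

    persons: pd.DataFrame
    claims: pd.DataFrame
    prescriptions: pd.DataFrame
    checkups: pd.DataFrame
    deaths: pd.DataFrame = field(default_factory=lambda: _empty_deaths())

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "persons": self.persons,
            "claims": self.claims,
            "prescriptions": self.prescriptions,
            "checkups": self.checkups,
            "deaths": self.deaths,
        }


def _empty_deaths() -> pd.DataFrame:
    return pd.DataFrame(
        {"person_id": pd.Series(dtype=int), "date": pd.Series(dtype=int),
         "cause_icd10": pd.Series(dtype=str)}
    )


@dataclass
class TruthOracle:
    """Monte-Carlo ground truth for the always- vs never-treated contrast."""

    params: SimParams
    hr_always_vs_never: float
    mc_reps: int
    mc_se: float  # SE of log(hr); the HR ratio scale band is exp(+-2*mc_se)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _stream(seed: int, name: str) -> np.random.Generator:
    """One independent RNG stream per logical table, stable under additions."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _draw_baseline(params: SimParams, rng: np.random.Generator):
    n = params.n_persons
    female = rng.random(n) < params.female_frac
    age = rng.normal(params.baseline_age_mean, params.baseline_age_sd, n)
    # adults only: the generator emits an eligible cohort; eligibility logic
    # is exercised on hand-built records
    age = np.clip(age, 19.0, 90.0)
    premium_band = rng.integers(1, 11, n)
    return female, age, premium_band


def _simulate_panel(params: SimParams, forced_treatment: int | None = None,
                    censoring: bool = True, rng: np.random.Generator | None = None):
    """Vectorized interval-by-interval simulation.

    Returns a dict of (n_intervals, n_persons) arrays plus baseline arrays.
    ``forced_treatment`` pins A_k to 0 or 1 for every interval (regime
    simulation); latent severity and event uniforms come from streams that do
    not depend on the regime, so regimes share random draws.
    """
    n, K = params.n_persons, params.n_intervals
    if rng is None:
        rng = _stream(params.seed, "latent")
    female, age, premium_band = _draw_baseline(params, rng)
    rho = params.severity_autocorr
    innov_sd = np.sqrt(1.0 - rho**2)

    base_logits = {
        c: np.log(p / (1 - p)) for c, p in params.comorbidity_emission_probs.items()
    }
    hosp_logit0 = np.log(_HOSP_BASE / (1 - _HOSP_BASE))

    S = np.empty((K, n))
    A = np.zeros((K, n), dtype=np.int8)
    Y = np.zeros((K, n), dtype=np.int8)
    C = np.zeros((K, len(COMORBIDITY_CLASSES), n), dtype=np.int8)
    H = np.zeros((K, n), dtype=np.int8)
    at_risk = np.zeros((K, n), dtype=bool)
    censored_in = np.full(n, -1)  # interval index after which admin censoring hits

    alive = np.ones(n, dtype=bool)
    a_prev = np.zeros(n, dtype=np.int8)
    s_prev = rng.normal(0.0, 1.0, n)
    for k in range(K):
        s = rho * s_prev + innov_sd * rng.normal(0.0, 1.0, n) if k else s_prev
        e = s + params.treatment_effect_on_severity * a_prev
        burden = np.zeros(n)
        for j, c in enumerate(COMORBIDITY_CLASSES):
            pc = _sigmoid(base_logits[c] + _COMORBIDITY_SLOPE * e)
            C[k, j] = rng.random(n) < pc
            burden += C[k, j]
        ph = _sigmoid(hosp_logit0 + _HOSP_SLOPE * e)
        H[k] = rng.random(n) < ph
        burden += H[k]

        logit_a = (
            _TREAT_INTERCEPT
            + params.severity_effect_on_treatment * burden
            + _TREAT_PERSISTENCE * a_prev
            + _TREAT_FEMALE * female
        )
        u_a = rng.random(n)
        if forced_treatment is None:
            a = (u_a < _sigmoid(logit_a)).astype(np.int8)
        else:
            a = np.full(n, forced_treatment, dtype=np.int8)

        logit_y = (
            params.baseline_event_logit
            + params.causal_log_hr * a
            + params.severity_effect_on_event * (s + _EVENT_BURDEN_FRAC * burden)
            + _EVENT_AGE_SLOPE * (age - 40.0)
            + _EVENT_FEMALE * female
        )
        y = (rng.random(n) < _sigmoid(logit_y)).astype(np.int8)

        at_risk[k] = alive
        A[k] = np.where(alive, a, 0)
        Y[k] = np.where(alive, y, 0)
        S[k] = s

        u_c = rng.random(n)  # drawn unconditionally to keep streams aligned
        if censoring:
            newly_censored = alive & (Y[k] == 0) & (u_c < params.censor_rate)
            censored_in[newly_censored & (censored_in < 0)] = k
            alive = alive & (Y[k] == 0) & ~newly_censored
        else:
            alive = alive & (Y[k] == 0)
        a_prev = A[k]
        s_prev = s

    return {
        "female": female,
        "age": age,
        "premium_band": premium_band,
        "S": S,
        "A": A,
        "Y": Y,
        "C": C,
        "H": H,
        "at_risk": at_risk,
        "censored_in": censored_in,
    }


def simulate_person_periods(params: SimParams) -> pd.DataFrame:
    """Directly emit the analysis-ready person-period long table.

    This is the fast path used by simulation studies: it bypasses claims
    emission and reconstruction, producing exactly the covariates the claims
    pipeline would recover (comorbidity-class indicators, hospitalization
    flag, baseline demographics, exposure, interval DDD and event status).
    Identical latent draws underlie :func:`generate_cohort`.
    """
    panel = _simulate_panel(params)
    n, K = params.n_persons, params.n_intervals
    mask = panel["at_risk"]  # (K, n)
    k_idx, person = np.nonzero(mask)

    dose_rng = _stream(params.seed, "dose")
    # interval dose in DDDs while treated: ~91 days at around 1 DDD/day
    dose_factor = np.exp(dose_rng.normal(-0.08, 0.4, size=(K, n)))
    interval_ddd_full = panel["A"] * INTERVAL_DAYS * dose_factor
    cum = np.cumsum(interval_ddd_full * mask, axis=0)

    a_prev_full = np.vstack([np.zeros((1, n), dtype=np.int8), panel["A"][:-1]])
    ever_prev_full = np.vstack(
        [np.zeros((1, n), dtype=np.int8), (np.cumsum(panel["A"], axis=0) > 0)[:-1]]
    ).astype(np.int8)

    df = pd.DataFrame(
        {
            "person_id": person,
            "k": k_idx,
            "female": panel["female"][person].astype(int),
            "age_at_index": panel["age"][person],
            "premium_band": panel["premium_band"][person],
            "A": panel["A"][k_idx, person].astype(int),
            "A_prev": a_prev_full[k_idx, person].astype(int),
            "ever_treated_prev": ever_prev_full[k_idx, person].astype(int),
            "psych_hosp": panel["H"][k_idx, person].astype(int),
            "interval_ddd": interval_ddd_full[k_idx, person] * 1.0,
            "cum_ddd": cum[k_idx, person],
            "Y": panel["Y"][k_idx, person].astype(int),
        }
    )
    for j, c in enumerate(COMORBIDITY_CLASSES):
        df[f"com_{c}"] = panel["C"][k_idx, j, person].astype(int)
    df = df.sort_values(["person_id", "k"], kind="mergesort").reset_index(drop=True)
    return df


def _interval_event_fraction(df: pd.DataFrame) -> float:
    return float(df["Y"].mean())


def generate_cohort(params: SimParams) -> RawRecords:
    """Emit claims-style raw tables for the simulated cohort.

    Every person indexes (first PTSD claim, code F43.1) at day 0; comorbidity
    and outcome claims, prescriptions and periodic check-ups are laid down in
    the 91-day interval where the latent panel produced them.  Follow-up for
    event-free persons ends with a final generic claim, so "last claim date"
    reconstructs the administrative censoring time.
    """
    panel = _simulate_panel(params)
    n, K = params.n_persons, params.n_intervals
    pid = np.arange(n)

    persons = pd.DataFrame(
        {
            "person_id": pid,
            "sex": np.where(panel["female"], "F", "M"),
            "birth_year": _ORIGIN_YEAR - np.round(panel["age"]).astype(int),
            "premium_band": panel["premium_band"],
        }
    )

    claims_rng = _stream(params.seed, "claims")
    rx_rng = _stream(params.seed, "prescriptions")
    chk_rng = _stream(params.seed, "checkups")

    claim_rows: list[tuple] = []  # person, date, code, setting, revasc, imaging, adm

    # index PTSD claim
    for i in pid:
        claim_rows.append((i, 0, PTSD_CODE, "outpatient", False, False, False))

    mask = panel["at_risk"]
    # comorbidity claims
    for j, c in enumerate(COMORBIDITY_CLASSES):
        k_idx, person = np.nonzero(panel["C"][:, j, :] & mask)
        days = k_idx * INTERVAL_DAYS + claims_rng.integers(0, INTERVAL_DAYS, k_idx.size)
        codes = claims_rng.integers(0, len(_EMITTED_CODES[c]), k_idx.size)
        for kk, pp, dd, cc in zip(k_idx, person, days, codes):
            claim_rows.append(
                (pp, int(dd), _EMITTED_CODES[c][cc], "outpatient", False, False, False)
            )
    # psychiatric hospitalizations
    k_idx, person = np.nonzero(panel["H"] & mask)
    days = k_idx * INTERVAL_DAYS + claims_rng.integers(0, INTERVAL_DAYS, k_idx.size)
    for kk, pp, dd in zip(k_idx, person, days):
        # F99 (mental disorder NOS): an admission claim outside the five
        # comorbidity code groups, so hospitalization and comorbidity flags
        # stay separately identified downstream
        claim_rows.append((pp, int(dd), "F99", "inpatient", False, False, True))

    # MACE events
    deaths_rows: list[tuple] = []
    k_idx, person = np.nonzero(panel["Y"] & mask)
    types = list(_MACE_TYPE_PROBS)
    probs = np.array([_MACE_TYPE_PROBS[t] for t in types])
    type_draw = claims_rng.choice(len(types), size=k_idx.size, p=probs)
    event_day = k_idx * INTERVAL_DAYS + claims_rng.integers(0, INTERVAL_DAYS, k_idx.size)
    event_record = {}
    for kk, pp, dd, tt in zip(k_idx, person, event_day, type_draw):
        t = types[tt]
        event_record[int(pp)] = (int(dd), t)
        if t == "cv_death":
            deaths_rows.append((int(pp), int(dd), "I46.1"))
        elif t == "CAD_revasc":
            # half plain MI, half other-IHD + revascularization in-session
            if claims_rng.random() < 0.5:
                claim_rows.append((pp, int(dd), "I21.0", "inpatient", False, False, True))
            else:
                claim_rows.append((pp, int(dd), "I20.0", "inpatient", True, False, True))
        elif t == "ischaemic_stroke":
            claim_rows.append((pp, int(dd), "I63.9", "inpatient", False, True, True))
        else:
            claim_rows.append((pp, int(dd), "I61.0", "inpatient", False, True, True))

    # end-of-follow-up marker claim for event-free persons
    last_at_risk = np.where(mask.any(axis=0), mask.shape[0] - 1 -
                            np.argmax(mask[::-1], axis=0), -1)
    for i in pid:
        if i in event_record:
            continue
        end_day = int((last_at_risk[i] + 1) * INTERVAL_DAYS - 1)
        claim_rows.append((i, end_day, "Z00.0", "outpatient", False, False, False))

    claims = pd.DataFrame(
        claim_rows,
        columns=["person_id", "date", "icd10_code", "setting",
                 "revascularization", "brain_imaging", "admission_flag"],
    )

    # prescriptions: one per treated person-interval
    from .exposure import load_ddd_table

    ddd = load_ddd_table().reset_index()
    by_class = {c: ddd[ddd["drug_class"] == c] for c in _DRUG_CLASS_PROBS}
    k_idx, person = np.nonzero(panel["A"] & mask)
    cls_names = list(_DRUG_CLASS_PROBS)
    cls_probs = np.array([_DRUG_CLASS_PROBS[c] for c in cls_names])
    cls_draw = rx_rng.choice(len(cls_names), size=k_idx.size, p=cls_probs)
    start_off = rx_rng.integers(0, 8, k_idx.size)
    dose_mult = rx_rng.choice([0.5, 1.0, 1.5, 2.0], size=k_idx.size,
                              p=[0.2, 0.5, 0.2, 0.1])
    rx_rows = []
    for kk, pp, cc, so, dm in zip(k_idx, person, cls_draw, start_off, dose_mult):
        pool = by_class[cls_names[cc]]
        drug = pool.iloc[int(rx_rng.integers(0, len(pool)))]
        start = int(kk) * INTERVAL_DAYS + int(so)
        days = min(84, params.n_intervals * INTERVAL_DAYS - start)
        rx_rows.append(
            (int(pp), start, drug["drug_code"], drug["drug_class"],
             float(dm * drug["who_ddd_mg"]), int(days))
        )
    prescriptions = pd.DataFrame(
        rx_rows,
        columns=["person_id", "start_date", "drug_code", "class",
                 "daily_dose_mg", "days_supplied"],
    )

    # check-ups: everyone at interval 0, then every 4th interval with p=0.6
    chk_rows = []
    for k in range(0, K, 4):
        if k == 0:
            who = pid
        else:
            eligible = pid[mask[k]]
            who = eligible[chk_rng.random(eligible.size) < 0.6]
        days = k * INTERVAL_DAYS + chk_rng.integers(0, INTERVAL_DAYS, who.size)
        vals = np.column_stack(
            [
                chk_rng.normal(23.5, 3.0, who.size),      # bmi
                chk_rng.normal(120.0, 13.0, who.size),    # sbp
                chk_rng.normal(76.0, 9.0, who.size),      # dbp
                chk_rng.normal(95.0, 18.0, who.size),     # fasting glucose
                chk_rng.normal(195.0, 35.0, who.size),    # total cholesterol
            ]
        )
        smoking = (chk_rng.random(who.size) < 0.25).astype(int)
        drinking = chk_rng.integers(0, 5, who.size)
        for idx, p in enumerate(who):
            chk_rows.append(
                (int(p), int(days[idx]), *np.round(vals[idx], 1),
                 int(smoking[idx]), int(drinking[idx]))
            )
    checkups = pd.DataFrame(
        chk_rows,
        columns=["person_id", "date", "bmi", "sbp", "dbp",
                 "fasting_glucose", "total_cholesterol", "smoking",
                 "drinking_freq"],
    )

    deaths = pd.DataFrame(deaths_rows, columns=["person_id", "date", "cause_icd10"]) \
        if deaths_rows else _empty_deaths()

    for tbl in (claims, prescriptions, checkups):
        tbl.sort_values(list(tbl.columns[:2]), kind="mergesort", inplace=True,
                        ignore_index=True)
    return RawRecords(persons=persons, claims=claims, prescriptions=prescriptions,
                      checkups=checkups, deaths=deaths)


def _pooled_log_or(events_1, atrisk_1, events_0, atrisk_0):
    if events_1 == 0 and events_0 == 0:
        raise EstimationError("no events under either regime; estimand undefined")
    if min(events_1, events_0) == 0 or events_1 == atrisk_1 or events_0 == atrisk_0:
        raise EstimationError("degenerate regime event counts; increase mc_n")
    h1 = events_1 / atrisk_1
    h0 = events_0 / atrisk_0
    log_or = np.log(h1 / (1 - h1)) - np.log(h0 / (1 - h0))
    se = np.sqrt(
        1.0 / events_1 + 1.0 / (atrisk_1 - events_1)
        + 1.0 / events_0 + 1.0 / (atrisk_0 - events_0)
    )
    return log_or, se


def counterfactual_truth(params: SimParams, mc_n: int = 100_000) -> TruthOracle:
    """Monte-Carlo ground truth: pooled discrete-time HR, always vs never.

    Simulates ``mc_n`` persons under the two deterministic regimes with
    shared random draws (the latent vulnerability path and event uniforms do
    not depend on the regime), without administrative censoring, and pools
    events over at-risk person-intervals.  The reported ``mc_se`` is the
    binomial standard error of the pooled log odds ratio; with shared draws
    it is conservative.
    """
    if mc_n < 10_000:
        raise ParameterError("mc_n must be >= 10000 for a stable oracle")
    p = SimParams(**{**params.to_dict(), "n_persons": int(mc_n)})
    rng1 = _stream(p.seed, "oracle")
    rng0 = _stream(p.seed, "oracle")  # identical stream -> shared draws
    always = _simulate_panel(p, forced_treatment=1, censoring=False, rng=rng1)
    never = _simulate_panel(p, forced_treatment=0, censoring=False, rng=rng0)
    e1 = int(always["Y"][always["at_risk"]].sum())
    n1 = int(always["at_risk"].sum())
    e0 = int(never["Y"][never["at_risk"]].sum())
    n0 = int(never["at_risk"].sum())
    log_or, se = _pooled_log_or(e1, n1, e0, n0)
    return TruthOracle(
        params=params,
        hr_always_vs_never=float(np.exp(log_or)),
        mc_reps=int(mc_n),
        mc_se=float(se),
    )
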