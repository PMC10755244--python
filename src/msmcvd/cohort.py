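"""Cohort eligibility and the person-period long table.

Eligibility mirrors a claims-cohort enrolment: persons index at their first
PTSD claim (ICD-10 F43.1) and are excluded, in order, if (i) aged 18 years
or younger at index, (ii) missing sociodemographic data (sex, birth year or
premium band), (iii) never health-checked, (iv) carrying a MACE diagnosis
before index, or (v) dispensed an antidepressant before index.

Follow-up is laid out in half-open 91-day intervals [91k, 91(k+1)) from the
index date (day 0), ending at the first MACE or the last insurance claim;
the final partial interval keeps its true length.  Time-varying covariates
update per interval; check-up values are carried forward from the most
recent measurement at or before the interval (LOCF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure import (DRUG_CLASSES, allocate_prescription_days,
                       cumulative_ddd, load_ddd_table)
from .outcomes import (IntegrityError, OutcomeCodeSets, classify_events,
                       mark_events)
from .simulate import COMORBIDITY_ICD10, _ORIGIN_YEAR

__all__ = ["EligibilityConfig", "ELIGIBILITY_RULES", "apply_eligibility",
           "build_person_periods", "person_level_table",
           "COVARIATE_COLUMNS", "COMORBIDITY_FLAG_COLUMNS"]

INTERVAL_DAYS = 91

ELIGIBILITY_RULES = (
    "i_age_18_or_younger",
    "ii_missing_sociodemographics",
    "iii_never_checked_up",
    "iv_prior_mace",
    "v_prior_antidepressant",
)

COMORBIDITY_FLAG_COLUMNS = tuple(f"com_{c}" for c in COMORBIDITY_ICD10)
CHECKUP_VALUE_COLUMNS = ("bmi", "sbp", "dbp", "fasting_glucose",
                         "total_cholesterol", "smoking", "drinking_freq")
COVARIATE_COLUMNS = COMORBIDITY_FLAG_COLUMNS + ("psych_hosp",) + CHECKUP_VALUE_COLUMNS


@dataclass(frozen=True)
class EligibilityConfig:
    ptsd_code: str = "F43.1"
    min_age_exclusive: float = 18.0
    require_checkup: bool = True

    def __post_init__(self):
        if not self.ptsd_code:
            raise ValueError("ptsd_code must be non-empty")
        if self.min_age_exclusive < 0:
            raise ValueError("min_age_exclusive must be >= 0")


def _index_dates(claims: pd.DataFrame, ptsd_code: str) -> pd.Series:
    ptsd = claims[claims["icd10_code"].astype(str).str.startswith(ptsd_code)]
    if ptsd["date"].isna().any():
        bad = ptsd.loc[ptsd["date"].isna(), "person_id"].iloc[0]
        raise IntegrityError(f"person {bad} has a PTSD claim without a valid date")
    return ptsd.groupby("person_id")["date"].min()


def apply_eligibility(raw, cfg: EligibilityConfig | None = None,
                      code_sets: OutcomeCodeSets | None = None):
    """Apply enrolment rules; returns (cohort frame, exclusion tally).

    The cohort frame holds person_id, index_date, sex, age_at_index and
    premium_band for retained persons.  The tally counts exclusions per rule
    applied sequentially in the listed order (a person failing several rules
    counts once, under the first).
    """
    cfg = cfg or EligibilityConfig()
    idx = _index_dates(raw.claims, cfg.ptsd_code)
    persons = raw.persons.set_index("person_id")
    tally = {r: 0 for r in ELIGIBILITY_RULES}
    kept = []

    pre_rx = raw.prescriptions.merge(
        idx.rename("index_date"), left_on="person_id", right_index=True
    )
    prior_rx_persons = set(
        pre_rx.loc[pre_rx["start_date"] < pre_rx["index_date"], "person_id"]
    )

    pre_claims = raw.claims.merge(
        idx.rename("index_date"), left_on="person_id", right_index=True
    )
    pre_claims = pre_claims[pre_claims["date"] < pre_claims["index_date"]]
    if len(pre_claims):
        prior_mace = set(classify_events(pre_claims, None, code_sets).index)
    else:
        prior_mace = set()

    checked = set(raw.checkups["person_id"].unique())

    rows = []
    for person_id, index_date in idx.sort_index().items():
        demo = persons.loc[person_id] if person_id in persons.index else None
        missing_demo = (
            demo is None
            or pd.isna(demo.get("sex"))
            or pd.isna(demo.get("birth_year"))
            or pd.isna(demo.get("premium_band"))
        )
        if not missing_demo:
            index_year = _ORIGIN_YEAR + int(index_date) // 365
            age = index_year - int(demo["birth_year"])
        else:
            age = np.nan
        if not missing_demo and age <= cfg.min_age_exclusive:
            tally["i_age_18_or_younger"] += 1
            continue
        if missing_demo:
            tally["ii_missing_sociodemographics"] += 1
            continue
        if cfg.require_checkup and person_id not in checked:
            tally["iii_never_checked_up"] += 1
            continue
        if person_id in prior_mace:
            tally["iv_prior_mace"] += 1
            continue
        if person_id in prior_rx_persons:
            tally["v_prior_antidepressant"] += 1
            continue
        rows.append(
            {
                "person_id": person_id,
                "index_date": int(index_date),
                "female": int(demo["sex"] == "F"),
                "age_at_index": float(age),
                "premium_band": demo["premium_band"],
            }
        )
    cohort = pd.DataFrame(
        rows, columns=["person_id", "index_date", "female", "age_at_index",
                       "premium_band"]
    )
    return cohort, tally


def _comorbidity_flags(claims_rel: pd.DataFrame, interval_days: int,
                       index_code: str = "F43.1") -> pd.DataFrame:
    """(person_id, k) -> per-class indicator, from F-coded claims.

    The cohort-defining index claim itself (rel day 0, the PTSD code) is the
    enrolment event, not a time-varying symptom record, and is skipped —
    otherwise the anxiety-class flag would be 1 for every person at k = 0.
    """
    claims_rel = claims_rel[
        ~((claims_rel["rel_date"] == 0)
          & claims_rel["icd10_code"].astype(str).str.startswith(index_code))
    ]
    frames = []
    codes = claims_rel["icd10_code"].astype(str)
    k = (claims_rel["rel_date"] // interval_days).astype(int)
    for cls, prefixes in COMORBIDITY_ICD10.items():
        m = pd.Series(False, index=claims_rel.index)
        for p in prefixes:
            m |= codes.str.startswith(p)
        if m.any():
            sub = pd.DataFrame(
                {"person_id": claims_rel.loc[m, "person_id"], "k": k[m]}
            ).drop_duplicates()
            sub[f"com_{cls}"] = 1
            frames.append(sub.set_index(["person_id", "k"]))
    hosp = claims_rel[
        codes.str.startswith("F") & claims_rel["admission_flag"].fillna(False).astype(bool)
    ]
    if len(hosp):
        sub = pd.DataFrame(
            {"person_id": hosp["person_id"],
             "k": (hosp["rel_date"] // interval_days).astype(int)}
        ).drop_duplicates()
        sub["psych_hosp"] = 1
        frames.append(sub.set_index(["person_id", "k"]))
    if not frames:
        return pd.DataFrame(
            index=pd.MultiIndex.from_arrays([[], []], names=["person_id", "k"])
        )
    return pd.concat(frames, axis=1).fillna(0).astype(int)


def build_person_periods(raw, cohort: pd.DataFrame,
                         interval_days: int = INTERVAL_DAYS,
                         ddd_table: pd.DataFrame | None = None,
                         code_sets: OutcomeCodeSets | None = None) -> pd.DataFrame:
    """Lay out one row per person per 91-day interval with exposure,
    covariates (LOCF), cumulative DDD and event status.

    Follow-up runs to the first MACE or the last claim; non-MACE
    cardiovascular diagnoses do not end follow-up.  Persons whose only
    record is the index claim receive a single interval row flagged
    ``degenerate``.
    """
    if ddd_table is None:
        ddd_table = load_ddd_table()
    idx = cohort.set_index("person_id")["index_date"]

    claims = raw.claims[raw.claims["person_id"].isin(idx.index)].copy()
    claims["rel_date"] = claims["date"] - claims["person_id"].map(idx)
    claims = claims[claims["rel_date"] >= 0]
    rx = raw.prescriptions[raw.prescriptions["person_id"].isin(idx.index)].copy()
    rx["rel_start"] = rx["start_date"] - rx["person_id"].map(idx)

    last_claim = claims.groupby("person_id")["rel_date"].max()
    last_rx = rx.groupby("person_id")["rel_start"].max()
    follow_end = last_claim.reindex(idx.index).astype(float).fillna(0.0)
    follow_end = np.maximum(
        follow_end, last_rx.reindex(idx.index).astype(float).fillna(0.0)
    )

    # base grid
    grids = []
    for person_id, end_rel in follow_end.items():
        n_iv = int(end_rel) // interval_days + 1
        ks = np.arange(n_iv)
        grids.append(
            pd.DataFrame(
                {
                    "person_id": person_id,
                    "k": ks,
                    "interval_start": ks * interval_days,
                    "interval_end": np.minimum(
                        (ks + 1) * interval_days, int(end_rel) + 1
                    ),
                    "degenerate": bool(end_rel == 0),
                }
            )
        )
    pp = pd.concat(grids, ignore_index=True)

    # exposure: per-person interval DDD by class, and any-overlap indicators
    n_iv_by_person = (follow_end // interval_days).astype(int) + 1
    a_flags: dict[tuple, int] = {}
    class_flags: dict[str, dict[tuple, int]] = {c: {} for c in DRUG_CLASSES}
    interval_ddd: dict[tuple, float] = {}
    class_ddd: dict[str, dict[tuple, float]] = {c: {} for c in DRUG_CLASSES}
    for row in rx.itertuples(index=False):
        if row.rel_start < 0:
            raise ValueError(
                f"prescription predating index for person {row.person_id}; "
                "eligibility should have excluded this person"
            )
        code = row.drug_code
        if code not in ddd_table.index:
            from .exposure import UnknownDrugError

            raise UnknownDrugError(code)
        who = float(ddd_table.loc[code, "who_ddd_mg"])
        cls = str(ddd_table.loc[code, "drug_class"])
        n_iv = int(n_iv_by_person[row.person_id])
        days = allocate_prescription_days(
            int(row.rel_start), int(row.days_supplied), n_iv, interval_days
        )
        ddd_per_day = row.daily_dose_mg / who
        for k in np.nonzero(days)[0]:
            key = (row.person_id, int(k))
            a_flags[key] = 1
            class_flags[cls][key] = 1
            interval_ddd[key] = interval_ddd.get(key, 0.0) + ddd_per_day * days[k]
            class_ddd[cls][key] = class_ddd[cls].get(key, 0.0) + ddd_per_day * days[k]

    key_index = pd.MultiIndex.from_frame(pp[["person_id", "k"]])
    pp["A"] = [a_flags.get(t, 0) for t in key_index]
    pp["interval_ddd"] = [interval_ddd.get(t, 0.0) for t in key_index]
    for c in ("SSRI", "SNRI", "TCA"):
        pp[f"A_{c}"] = [class_flags[c].get(t, 0) for t in key_index]
        pp[f"interval_ddd_{c}"] = [class_ddd[c].get(t, 0.0) for t in key_index]

    # comorbidity flags from claims within each interval
    flags = _comorbidity_flags(claims, interval_days)
    for col in list(COMORBIDITY_FLAG_COLUMNS) + ["psych_hosp"]:
        if col in flags.columns:
            pp[col] = (
                flags[col].reindex(key_index).fillna(0).astype(int).to_numpy()
            )
        else:
            pp[col] = 0

    # check-up covariates: LOCF from most recent record at or before interval end
    chk = raw.checkups[raw.checkups["person_id"].isin(idx.index)].copy()
    if len(chk):
        chk["rel_date"] = chk["date"] - chk["person_id"].map(idx)
        chk = chk[chk["rel_date"] >= 0].sort_values(["rel_date", "person_id"],
                                                    kind="mergesort")
        probe = pp[["person_id", "interval_end"]].copy()
        probe["probe_day"] = probe["interval_end"] - 1
        probe = probe.sort_values(["probe_day", "person_id"], kind="mergesort")
        merged = pd.merge_asof(
            probe,
            chk[["person_id", "rel_date", *CHECKUP_VALUE_COLUMNS]],
            left_on="probe_day", right_on="rel_date", by="person_id",
            direction="backward",
        ).set_index(probe.index)
        for col in CHECKUP_VALUE_COLUMNS:
            pp[col] = merged[col].reindex(pp.index)
    else:
        for col in CHECKUP_VALUE_COLUMNS:
            pp[col] = np.nan
    pp["current_drinker"] = (pp["drinking_freq"] >= 1).astype(int)

    # baseline block
    pp = pp.merge(cohort[["person_id", "female", "age_at_index", "premium_band"]],
                  on="person_id", how="left")

    # cumulative DDD (non-decreasing within person)
    pp = pp.sort_values(["person_id", "k"], kind="mergesort").reset_index(drop=True)
    pp["cum_ddd"] = pp.groupby("person_id")["interval_ddd"].cumsum()
    for c in ("SSRI", "SNRI", "TCA"):
        pp[f"cum_ddd_{c}"] = pp.groupby("person_id")[f"interval_ddd_{c}"].cumsum()

    # treatment history encodings
    grp = pp.groupby("person_id")["A"]
    pp["A_prev"] = grp.shift(1).fillna(0).astype(int)
    pp["ever_treated_prev"] = (
        grp.cumsum().groupby(pp["person_id"]).shift(1).fillna(0) > 0
    ).astype(int)

    # events
    events = classify_events(claims.assign(date=claims["rel_date"]),
                             _rel_deaths(raw, idx), code_sets)
    pp = mark_events(pp, events, interval_days=interval_days)
    return pp


def _rel_deaths(raw, idx):
    deaths = getattr(raw, "deaths", None)
    if deaths is None or not len(deaths):
        return None
    dd = deaths[deaths["person_id"].isin(idx.index)].copy()
    dd["date"] = dd["date"] - dd["person_id"].map(idx)
    return dd[dd["date"] >= 0]


def person_level_table(person_periods: pd.DataFrame,
                       interval_days: int = INTERVAL_DAYS) -> pd.DataFrame:
    """Collapse to one row per person for time-fixed survival analysis.

    Exposure is ever-vs-never over follow-up; covariates are the baseline
    (k = 0) values; time is days to event or censoring.
    """
    pp = person_periods.sort_values(["person_id", "k"], kind="mergesort")
    first = pp.groupby("person_id").first()
    last = pp.groupby("person_id").last()
    out = pd.DataFrame(index=first.index)
    out["ever_exposed"] = pp.groupby("person_id")["A"].max()
    out["event"] = last["Y"]
    if "interval_end" in pp.columns:
        out["duration_days"] = last["interval_end"]
    else:
        out["duration_days"] = (last["k"] + 1) * interval_days
    for col in ("female", "age_at_index", "premium_band"):
        if col in first.columns:
            out[col] = first[col]
    for col in COVARIATE_COLUMNS + ("current_drinker",):
        if col in first.columns:
            out[f"baseline_{col}"] = first[col]
    return out.reset_index()
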