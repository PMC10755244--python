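"""MACE adjudication from claims.

The composite outcome is the first of: coronary artery disease with
revascularization (ICD-10 I21, or I20/I24 with a revascularization procedure
in the same treatment session), ischaemic stroke (I63 with brain imaging in
session), haemorrhagic stroke (I60/I61/I62 with brain imaging in session),
or cardiovascular death (cause of death in chapter I).  Outpatient
diagnoses never qualify; only inpatient and emergency-department claims do.
A "treatment session" is operationalized as the claim row itself carrying
its procedure flags (claims sharing an admission are pre-merged upstream).
Non-MACE cardiovascular diagnoses do not end follow-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OutcomeCodeSets", "EVENT_TYPES", "classify_events", "mark_events",
           "IntegrityError"]

log = logging.getLogger(__name__)

EVENT_TYPES = ("CAD_revasc", "ischaemic_stroke", "haemorrhagic_stroke", "cv_death")

INTERVAL_DAYS = 91


class IntegrityError(ValueError):
    """Claims data violate a structural requirement of adjudication."""


@dataclass(frozen=True)
class OutcomeCodeSets:
    """ICD-10 prefixes defining the composite; prefix match includes sub-codes."""

    mi_codes: tuple = ("I21",)
    other_ihd_codes: tuple = ("I20", "I24")
    ischaemic_stroke_codes: tuple = ("I63",)
    haemorrhagic_stroke_codes: tuple = ("I60", "I61", "I62")
    cv_death_prefix: str = "I"
    allowed_settings: tuple = ("inpatient", "emergency")


def _matches(codes: pd.Series, prefixes: tuple) -> pd.Series:
    out = pd.Series(False, index=codes.index)
    for p in prefixes:
        out |= codes.str.startswith(p)
    return out


def classify_events(claims: pd.DataFrame, deaths: pd.DataFrame | None = None,
                    code_sets: OutcomeCodeSets | None = None) -> pd.DataFrame:
    """First qualifying MACE per person.

    Returns a frame indexed by person_id with columns ``date`` and
    ``event_type``; persons without MACE are absent.  Same-day qualifying
    events of different types resolve by the fixed precedence
    CAD_revasc > ischaemic > haemorrhagic > cv_death (logged).
    """
    cs = code_sets or OutcomeCodeSets()
    candidates = []

    cl = claims.copy()
    cl["icd10_code"] = cl["icd10_code"].astype(str)
    stroke_codes = cs.ischaemic_stroke_codes + cs.haemorrhagic_stroke_codes
    is_stroke = _matches(cl["icd10_code"], stroke_codes)
    if is_stroke.any() and cl.loc[is_stroke, "brain_imaging"].isna().any():
        bad = cl.loc[is_stroke & cl["brain_imaging"].isna()].iloc[0]
        raise IntegrityError(
            "stroke claim without session imaging information: person "
            f"{bad['person_id']} at day {bad['date']}"
        )

    inp = cl[cl["setting"].isin(cs.allowed_settings)]
    if len(inp):
        codes = inp["icd10_code"]
        cad = _matches(codes, cs.mi_codes) | (
            _matches(codes, cs.other_ihd_codes)
            & inp["revascularization"].fillna(False).astype(bool)
        )
        isch = _matches(codes, cs.ischaemic_stroke_codes) & \
            inp["brain_imaging"].fillna(False).astype(bool)
        haem = _matches(codes, cs.haemorrhagic_stroke_codes) & \
            inp["brain_imaging"].fillna(False).astype(bool)
        for mask, etype in ((cad, "CAD_revasc"), (isch, "ischaemic_stroke"),
                            (haem, "haemorrhagic_stroke")):
            sub = inp.loc[mask, ["person_id", "date"]]
            if len(sub):
                candidates.append(sub.assign(event_type=etype))

    if deaths is not None and len(deaths):
        dd = deaths[deaths["cause_icd10"].astype(str).str.startswith(cs.cv_death_prefix)]
        if len(dd):
            candidates.append(
                dd[["person_id", "date"]].assign(event_type="cv_death")
            )

    if not candidates:
        return pd.DataFrame(columns=["date", "event_type"],
                            index=pd.Index([], name="person_id"))

    allc = pd.concat(candidates, ignore_index=True)
    prec = {t: i for i, t in enumerate(EVENT_TYPES)}
    allc["prec"] = allc["event_type"].map(prec)
    allc = allc.sort_values(["person_id", "date", "prec"], kind="mergesort")
    ties = allc.duplicated(subset=["person_id", "date"], keep=False)
    first = allc.groupby("person_id", sort=True).first()
    if ties.any():
        tied_persons = allc.loc[ties, "person_id"].unique()
        affected = [p for p in tied_persons
                    if allc[(allc["person_id"] == p)
                            & (allc["date"] == first.loc[p, "date"])]["event_type"]
                    .nunique() > 1]
        if affected:
            log.warning(
                "same-day qualifying events of different types for persons %s; "
                "resolved by fixed precedence %s", affected, EVENT_TYPES
            )
    return first[["date", "event_type"]]


def mark_events(person_periods: pd.DataFrame, events: pd.DataFrame,
                index_dates: pd.Series | None = None,
                interval_days: int = INTERVAL_DAYS) -> pd.DataFrame:
    """Set Y/event_type on the person-period table; truncate at the event.

    ``events`` is the output of :func:`classify_events` with dates in days
    from index (or absolute, with ``index_dates`` supplied for conversion).
    The event lands in the half-open interval containing its day; rows after
    it are removed, so each person has at most one Y = 1 row, in their last.
    """
    pp = person_periods.copy()
    pp["Y"] = 0
    pp["event_type"] = "none"
    if not len(events):
        return pp
    keep = np.ones(len(pp), dtype=bool)
    for person, row in events.iterrows():
        day = row["date"]
        if index_dates is not None:
            day = day - index_dates.loc[person]
        if day < 0:
            raise ValueError(
                f"event before index for person {person}; eligibility should "
                "have excluded prior MACE"
            )
        k_event = int(day // interval_days)
        sel = pp["person_id"] == person
        if not sel.any():
            continue
        k_max = int(pp.loc[sel, "k"].max())
        k_event = min(k_event, k_max)  # event recorded past last claim: clamp
        keep &= ~(sel.to_numpy() & (pp["k"] > k_event).to_numpy())
        hit = sel & (pp["k"] == k_event)
        pp.loc[hit, "Y"] = 1
        pp.loc[hit, "event_type"] = row["event_type"]
    return pp.loc[keep].reset_index(drop=True)
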