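import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from msmcvd import SimParams, simulate_person_periods
from msmcvd.simulate import RawRecords

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(n_persons=800, n_intervals=6, seed=901)


@pytest.fixture(scope="session")
def medium_pp() -> pd.DataFrame:
    """Shared mid-size simulated person-period table (8 intervals)."""
    return simulate_person_periods(SimParams(n_persons=4000, n_intervals=8,
                                             seed=101))


def _person(pid, sex="F", birth_year=1980, premium_band=5):
    return dict(person_id=pid, sex=sex, birth_year=birth_year,
                premium_band=premium_band)


def _claim(pid, date, code, setting="outpatient", revasc=False, imaging=False,
           admission=False):
    return dict(person_id=pid, date=date, icd10_code=code, setting=setting,
                revascularization=revasc, brain_imaging=imaging,
                admission_flag=admission)


def _rx(pid, start, code="N06AB03", dose=20.0, days=30):
    return dict(person_id=pid, start_date=start, drug_code=code,
                **{"class": "SSRI"}, daily_dose_mg=dose, days_supplied=days)


def _checkup(pid, date, **kw):
    base = dict(person_id=pid, date=date, bmi=23.0, sbp=120.0, dbp=80.0,
                fasting_glucose=95.0, total_cholesterol=190.0, smoking=0,
                drinking_freq=1)
    base.update(kw)
    return base


@pytest.fixture()
def raw_eight_persons() -> RawRecords:
    """Hand-built enrolment fixture: one person violating each rule, three clean.

    Index is each person's first F43.1 claim.  Persons:
      0 clean; 1 clean; 2 clean;
      3 aged exactly 18 at index (rule i);
      4 missing premium band (rule ii);
      5 never checked up (rule iii);
      6 inpatient I21 ten days before index (rule iv);
      7 antidepressant dispensed before index (rule v).
    """
    index_day = 400  # year 2005 -> age = 2005 - birth_year
    persons = [
        _person(0), _person(1, sex="M"), _person(2),
        _person(3, birth_year=2005 - 18),
        _person(4, premium_band=np.nan),
        _person(5), _person(6), _person(7),
    ]
    claims = [_claim(p, index_day, "F43.1") for p in range(8)]
    claims += [_claim(p, 900, "Z00.0") for p in range(8)]  # follow-up marker
    claims.append(_claim(6, index_day - 10, "I21.0", setting="inpatient",
                         admission=True))
    rxs = [_rx(7, index_day - 30)]
    checkups = [_checkup(p, index_day + 1) for p in range(8) if p != 5]
    return RawRecords(
        persons=pd.DataFrame(persons),
        claims=pd.DataFrame(claims),
        prescriptions=pd.DataFrame(rxs),
        checkups=pd.DataFrame(checkups),
    )


@pytest.fixture()
def make_raw():
    """Factory for bespoke small RawRecords tables."""

    def _make(persons=(), claims=(), prescriptions=(), checkups=()):
        rx_cols = ["person_id", "start_date", "drug_code", "class",
                   "daily_dose_mg", "days_supplied"]
        chk_cols = ["person_id", "date", "bmi", "sbp", "dbp",
                    "fasting_glucose", "total_cholesterol", "smoking",
                    "drinking_freq"]
        claim_cols = ["person_id", "date", "icd10_code", "setting",
                      "revascularization", "brain_imaging", "admission_flag"]
        return RawRecords(
            persons=pd.DataFrame(list(persons) or [],
                                 columns=["person_id", "sex", "birth_year",
                                          "premium_band"]),
            claims=pd.DataFrame(list(claims) or [], columns=claim_cols),
            prescriptions=pd.DataFrame(list(prescriptions) or [],
                                       columns=rx_cols),
            checkups=pd.DataFrame(list(checkups) or [], columns=chk_cols),
        )

    return _make


@pytest.fixture()
def helpers():
    class H:
        person = staticmethod(_person)
        claim = staticmethod(_claim)
        rx = staticmethod(_rx)
        checkup = staticmethod(_checkup)

    return H
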