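"""Antidepressant exposure: WHO defined daily doses and cumulative dosing.

A prescription's dose in DDD units is ``daily_dose_mg * days_supplied /
who_ddd_mg``; interval-level exposure allocates a prescription's DDDs to the
91-day intervals it overlaps, pro-rata by days, and the cumulative series is
its running sum, updated every interval.  The dose–response models use
``log(1 + cumulative DDD)`` so never-treated person-periods (dose zero) stay
in the model at a transformed dose of exactly zero.

The packaged reference table (``data/ddd_reference.csv``) carries WHO ATC
DDD values for exemplar SSRIs, SNRIs, TCAs and other antidepressants
(e.g. N06AB03 fluoxetine 20 mg, N06AX21 duloxetine 60 mg, N06AA09
amitriptyline 75 mg).  Unknown drug codes raise: silent misclassification
would corrupt dose integrity.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "DRUG_CLASSES",
    "UnknownDrugError",
    "load_ddd_table",
    "prescription_ddd",
    "allocate_prescription_days",
    "interval_ddd_series",
    "cumulative_ddd",
    "log_cum_ddd",
]

DRUG_CLASSES = ("SSRI", "SNRI", "TCA", "other")

INTERVAL_DAYS = 91


class UnknownDrugError(KeyError):
    """Drug code absent from the DDD reference table."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self):
        return f"drug code {self.code!r} is not in the DDD reference table"


def load_ddd_table(path=None) -> pd.DataFrame:
    """Load a DDD table (drug_code, drug_class, who_ddd_mg), indexed by code."""
    if path is None:
        with resources.files("msmcvd.data").joinpath("ddd_reference.csv").open() as fh:
            tbl = pd.read_csv(fh)
    else:
        tbl = pd.read_csv(path)
    required = {"drug_code", "drug_class", "who_ddd_mg"}
    missing = required - set(tbl.columns)
    if missing:
        raise ValueError(f"DDD table missing columns: {sorted(missing)}")
    if (tbl["who_ddd_mg"] <= 0).any():
        raise ValueError("who_ddd_mg must be positive")
    bad = set(tbl["drug_class"]) - set(DRUG_CLASSES)
    if bad:
        raise ValueError(f"unknown drug classes in DDD table: {sorted(bad)}")
    return tbl.set_index("drug_code")


def prescription_ddd(daily_dose_mg: float, days_supplied: float,
                     who_ddd_mg: float) -> float:
    """DDD content of one prescription: dose * days / WHO DDD."""
    for name, v in (("daily_dose_mg", daily_dose_mg),
                    ("days_supplied", days_supplied),
                    ("who_ddd_mg", who_ddd_mg)):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    return daily_dose_mg * days_supplied / who_ddd_mg


def allocate_prescription_days(start_day: int, days_supplied: int,
                               n_intervals: int,
                               interval_days: int = INTERVAL_DAYS) -> np.ndarray:
    """Days of a prescription falling in each interval [k*L, (k+1)*L).

    Days past the administrative horizon are dropped; the allocation
    otherwise conserves ``days_supplied``.
    """
    if days_supplied <= 0:
        raise ValueError("days_supplied must be positive")
    out = np.zeros(n_intervals)
    end_day = start_day + days_supplied  # exclusive
    for k in range(n_intervals):
        lo, hi = k * interval_days, (k + 1) * interval_days
        overlap = min(end_day, hi) - max(start_day, lo)
        if overlap > 0:
            out[k] = overlap
    return out


def interval_ddd_series(prescriptions: pd.DataFrame, n_intervals: int,
                        ddd_table: pd.DataFrame,
                        interval_days: int = INTERVAL_DAYS,
                        by_class: bool = False):
    """Per-interval DDDs for one person's prescriptions (days from index).

    ``prescriptions`` needs columns start_day, drug_code, daily_dose_mg,
    days_supplied.  Prescriptions starting before day 0 raise (prior
    antidepressant use is an eligibility exclusion).  With ``by_class``,
    returns a (n_intervals, classes) DataFrame whose rows sum to the
    all-class series.
    """
    total = np.zeros(n_intervals)
    per_class = {c: np.zeros(n_intervals) for c in DRUG_CLASSES}
    for row in prescriptions.itertuples(index=False):
        if row.start_day < 0:
            raise ValueError(
                f"prescription at day {row.start_day} predates the index date; "
                "eligibility should have excluded this person"
            )
        code = row.drug_code
        if code not in ddd_table.index:
            raise UnknownDrugError(code)
        who = float(ddd_table.loc[code, "who_ddd_mg"])
        cls = str(ddd_table.loc[code, "drug_class"])
        ddd_per_day = row.daily_dose_mg / who
        days = allocate_prescription_days(
            int(row.start_day), int(row.days_supplied), n_intervals, interval_days
        )
        total += ddd_per_day * days
        per_class[cls] += ddd_per_day * days
    if by_class:
        return pd.DataFrame(per_class)
    return total


def cumulative_ddd(interval_ddd: np.ndarray) -> np.ndarray:
    """Running total of interval DDDs: non-decreasing by construction."""
    arr = np.asarray(interval_ddd, dtype=float)
    if (arr < 0).any():
        raise ValueError("interval DDD values must be nonnegative")
    return np.cumsum(arr)


def log_cum_ddd(cum_ddd):
    """Dose transform log(1 + cumulative DDD); maps zero dose to zero."""
    arr = np.asarray(cum_ddd, dtype=float)
    if (arr < 0).any():
        raise ValueError("cumulative DDD must be nonnegative")
    out = np.log1p(arr)
    return float(out) if np.isscalar(cum_ddd) else out
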