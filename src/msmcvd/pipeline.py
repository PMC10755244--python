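"""Configuration, file I/O and the end-to-end analysis driver.

``run_pipeline`` chains simulate -> eligibility -> person-periods ->
IPT weights -> MSM and Cox comparators -> dose–response -> sensitivity into
one run directory containing every intermediate table, the config snapshot
and a deterministic ``summary.json`` (same config and seed, byte-identical
summary).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (EligibilityConfig, apply_eligibility,
                     build_person_periods, person_level_table)
from .exposure import load_ddd_table, log_cum_ddd
from .iptw import (TreatmentModelSpec, compute_weights, dose_exposure_weights,
                   fit_treatment_models, weight_diagnostics)
from .msm import (fit_cox_time_fixed, fit_cox_time_varying, fit_msm,
                  fit_naive_time_varying, standardized_regime_hr)
from .sensitivity import (DEFAULT_TRUNCATION_PAIRS, evalue_ci,
                          truncation_sweep)
from .simulate import RawRecords, SimParams, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "read_raw", "write_raw",
           "write_person_periods", "read_person_periods", "SchemaError"]

log = logging.getLogger(__name__)

_RAW_SCHEMAS = {
    "persons": ("person_id", "sex", "birth_year", "premium_band"),
    "claims": ("person_id", "date", "icd10_code", "setting",
               "revascularization", "brain_imaging", "admission_flag"),
    "prescriptions": ("person_id", "start_date", "drug_code", "class",
                      "daily_dose_mg", "days_supplied"),
    "checkups": ("person_id", "date", "bmi", "sbp", "dbp", "fasting_glucose",
                 "total_cholesterol", "smoking", "drinking_freq"),
    "deaths": ("person_id", "date", "cause_icd10"),
}


class SchemaError(ValueError):
    """A table violates its documented CSV schema."""


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    sim: SimParams = field(default_factory=SimParams)
    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    treatment_model: TreatmentModelSpec = field(default_factory=TreatmentModelSpec)
    truncation_pairs: tuple = DEFAULT_TRUNCATION_PAIRS
    dose_response: bool = True
    ddd_table: str | None = None  # None -> packaged WHO reference table
    seed: int = 20230
    verbosity: int = 1  # 0 quiet, 1 info, 2 debug

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truncation_pairs"] = [list(p) for p in self.truncation_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimParams(**d["sim"])
        if "eligibility" in d:
            d["eligibility"] = EligibilityConfig(**d["eligibility"])
        if "treatment_model" in d:
            tm = dict(d["treatment_model"])
            for key in ("baseline_covariates", "time_varying_covariates",
                        "history"):
                if key in tm:
                    tm[key] = tuple(tm[key])
            d["treatment_model"] = TreatmentModelSpec(**tm)
        if "truncation_pairs" in d:
            d["truncation_pairs"] = tuple(tuple(p) for p in d["truncation_pairs"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_schema(name: str, df: pd.DataFrame) -> None:
    cols = _RAW_SCHEMAS[name]
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{name}: missing columns {sorted(missing)}")
    key_cols = cols[:2]
    for c in key_cols:
        if df[c].isna().any():
            rows = list(df.index[df[c].isna()][:5])
            raise SchemaError(f"{name}: null {c!r} at rows {rows}")
    if name == "claims" and df["setting"].isna().any():
        rows = list(df.index[df["setting"].isna()][:5])
        raise SchemaError(f"claims: missing setting at rows {rows}")


def write_raw(raw: RawRecords, out_dir, params: SimParams | None = None) -> None:
    """Write the four claims tables (+ deaths) as CSVs with a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in raw.tables().items():
        _check_schema(name, df)
        df.to_csv(out / f"{name}.csv", index=False)
    if params is not None:
        (out / "sim_params.json").write_text(
            json.dumps(params.to_dict(), indent=2, sort_keys=True)
        )


def read_raw(in_dir) -> RawRecords:
    """Read claims tables written by :func:`write_raw` (round-trip identity)."""
    p = Path(in_dir)
    tables = {}
    for name in _RAW_SCHEMAS:
        path = p / f"{name}.csv"
        if name == "deaths" and not path.exists():
            continue
        df = pd.read_csv(path)
        if len(df):
            _check_schema(name, df)
        tables[name] = df
    return RawRecords(**tables)


def write_person_periods(pp: pd.DataFrame, path) -> None:
    """Person-period CSV plus a JSON schema manifest next to it."""
    path = Path(path)
    pp.to_csv(path, index=False)
    manifest = {
        "columns": {c: str(pp[c].dtype) for c in pp.columns},
        "n_rows": int(len(pp)),
        "n_persons": int(pp["person_id"].nunique()),
    }
    path.with_suffix(".schema.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )


def read_person_periods(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _hr_entry(fit) -> dict:
    row = fit.hazard_ratios().iloc[0]
    return {
        "hr": round(float(row["hr"]), 6),
        "ci_low": round(float(row["ci_low"]), 6),
        "ci_high": round(float(row["ci_high"]), 6),
        "n_events": int(fit.n_events),
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full analysis; returns the summary dict (also on disk).

    The summary juxtaposes the time-fixed Cox, time-varying Cox and MSM
    hazard ratios, the dose–response estimate, weight diagnostics, the
    truncation sweep and e-values; every artifact lands under ``out_dir``.
    """
    if config.ddd_table is not None and not Path(config.ddd_table).exists():
        raise FileNotFoundError(
            f"configured DDD table {config.ddd_table!r} does not exist"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    level = {0: logging.WARNING, 1: logging.INFO}.get(config.verbosity,
                                                      logging.DEBUG)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s "
                                           "%(levelname)s %(message)s"))
    root = logging.getLogger("msmcvd")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(level)
    stage = "simulate"
    try:
        params = replace(config.sim, seed=config.seed)
        raw = generate_cohort(params)
        write_raw(raw, out / "raw", params)

        stage = "build-cohort"
        cohort, tally = apply_eligibility(raw, config.eligibility)
        if not len(cohort):
            raise RuntimeError("eligibility produced an empty cohort")
        pp = build_person_periods(raw, cohort,
                                  ddd_table=load_ddd_table(config.ddd_table))
        write_person_periods(pp, out / "person_periods.csv")

        stage = "weights"
        models = fit_treatment_models(pp, config.treatment_model)
        ws = compute_weights(pp, models)
        ws.frame.to_csv(out / "weights.csv", index=False)
        diag = weight_diagnostics(ws)
        diag.to_csv(out / "weight_diagnostics.csv")

        stage = "fit"
        msm = fit_msm(pp, weights=ws, exposure_cols=("A", "A_prev"))
        naive = fit_naive_time_varying(pp)
        cox_fixed = fit_cox_time_fixed(person_level_table(pp))
        cox_tv = fit_cox_time_varying(
            pp, time_varying_covariates=tuple(
                config.treatment_model.time_varying_covariates
            ),
        )

        dose_entry = None
        if config.dose_response:
            stage = "dose-response"
            dws = dose_exposure_weights(pp, config.treatment_model)
            dpp = pp.assign(log_cum_ddd=log_cum_ddd(pp["cum_ddd"].to_numpy()))
            dose_fit = fit_msm(dpp, weights=dws, exposure_cols=("log_cum_ddd",),
                               label="dose_response")
            dose_entry = _hr_entry(dose_fit)
            dose_diag = weight_diagnostics(dws)
            dose_diag.to_csv(out / "dose_weight_diagnostics.csv")

        stage = "sensitivity"
        sweep = truncation_sweep(pp, ws, config.truncation_pairs,
                                 exposure_cols=("A", "A_prev"))
        sweep.to_csv(out / "truncation_sweep.csv", index=False)
        main_hr = msm.hazard_ratios().iloc[0]
        ev = evalue_ci(float(main_hr["hr"]), float(main_hr["ci_low"]),
                       float(main_hr["ci_high"])).rounded()
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (artifacts so far in {out})"
        ) from err
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(old_level)

    diag0 = diag.iloc[0]
    summary = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "seed": int(config.seed),
        "n_source_persons": int(len(raw.persons)),
        "exclusion_tally": {k: int(v) for k, v in tally.items()},
        "n_cohort": int(len(cohort)),
        "n_person_periods": int(len(pp)),
        "n_events": int(pp["Y"].sum()),
        "hazard_ratios": {
            "cox_time_fixed": _hr_entry(cox_fixed),
            "cox_time_varying": _hr_entry(cox_tv),
            "pooled_logistic_time_varying": _hr_entry(naive),
            "msm_iptw": _hr_entry(msm),
        },
        "msm_marginal_hr_always_vs_never": round(
            float(standardized_regime_hr(msm, pp)), 6
        ),
        "dose_response_per_log_ddd": dose_entry,
        "weight_diagnostics_baseline": {
            "mean_log_sw": round(float(diag0["mean_log_sw"]), 6),
            "sd_log_sw": round(float(diag0["sd_log_sw"]), 6),
            "mean_log_w": round(float(diag0["mean_log_w"]), 6),
            "sd_log_w": round(float(diag0["sd_log_w"]), 6),
        },
        "truncation_sweep": [
            {k: (round(float(v), 6) if isinstance(v, float) else int(v))
             for k, v in row.items()}
            for row in sweep.to_dict("records")
        ],
        "evalues": {
            "point": ev.evalue_point,
            "ci_limit": ev.evalue_ci,
        },
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True)
    )
    log.info("run complete: %d persons, %d events, summary at %s",
             summary["n_cohort"], summary["n_events"], out / "summary.json")
    return summary
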