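"""Cohort domain types and delimited-text I/O.

A cohort is a flat comma-delimited UTF-8 table, one row per participant
(the "wide" dialect): demographics and labs in named columns and the two
5-point OGTT series as ``glucose_0 ... glucose_120`` and
``insulin_0 ... insulin_120`` (minutes in the suffix).  Optional follow-up
columns use a ``followup_`` prefix.  A "long" dialect with one row per
(participant, time) is also accepted and pivoted on read.

Validation mirrors the study's inclusion rules: participants need a
complete 10-value OGTT, an HbA1c, and BMI percentile >= 85; rows failing
validation are reported with their row index and reason, never dropped
silently.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .smoothing import DEFAULT_TIMES

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
RACES = ("white", "black", "other/multiracial", "unknown")
ETHNICITIES = ("hispanic", "non-hispanic")

TIME_SUFFIXES = [int(t) for t in DEFAULT_TIMES]


class CohortSchemaError(ValueError):
    """The input file is missing required columns for the chosen schema."""


@dataclass(frozen=True)
class OGTTProfile:
    """Five timed glucose and insulin measurements from one OGTT."""

    glucose: np.ndarray
    insulin: np.ndarray
    times: np.ndarray = field(default_factory=lambda: DEFAULT_TIMES.copy())

    def __post_init__(self):
        object.__setattr__(self, "glucose", np.asarray(self.glucose, float))
        object.__setattr__(self, "insulin", np.asarray(self.insulin, float))
        object.__setattr__(self, "times", np.asarray(self.times, float))

    def validate(self) -> None:
        for name, vals in (("glucose", self.glucose), ("insulin", self.insulin)):
            if vals.size != self.times.size:
                raise ValueError(f"incomplete OGTT: {name} has {vals.size} values")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"incomplete OGTT: non-finite {name} values")
            if np.any(vals <= 0):
                raise ValueError(f"non-positive {name} values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times not strictly increasing")

    @property
    def fpg(self) -> float:
        """Fasting plasma glucose: the 0-min value (mg/dL)."""
        return float(self.glucose[0])

    @property
    def pg2h(self) -> float:
        """2-hour plasma glucose: the 120-min value (mg/dL)."""
        return float(self.glucose[-1])


# lab/vital fields that may be missing for some participants
OPTIONAL_LABS = ("waist_cm", "sbp", "dbp", "total_chol", "ldl", "hdl",
                 "triglycerides")


@dataclass
class ParticipantRecord:
    """Demographics, labs and OGTT profiles for one participant."""

    id: str
    age: float
    sex: str
    race: str
    ethnicity: str
    bmi_percentile: float
    hba1c: float
    baseline_profile: OGTTProfile
    waist_cm: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    total_chol: float | None = None
    ldl: float | None = None
    hdl: float | None = None
    triglycerides: float | None = None
    followup_profile: OGTTProfile | None = None
    followup_interval: float | None = None  # months

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.race not in RACES:
            raise ValueError(f"unknown race {self.race!r}")
        if self.ethnicity not in ETHNICITIES:
            raise ValueError(f"unknown ethnicity {self.ethnicity!r}")
        if not np.isfinite(self.age) or not 0 < self.age < 120:
            raise ValueError(f"implausible age {self.age}")
        if not np.isfinite(self.bmi_percentile) or not (
            0 <= self.bmi_percentile <= 100
        ):
            raise ValueError(f"BMI percentile out of range: {self.bmi_percentile}")
        if self.bmi_percentile < 85:
            raise ValueError(
                f"BMI percentile {self.bmi_percentile} below 85th "
                "(inclusion threshold)"
            )
        if self.hba1c is None or not np.isfinite(self.hba1c):
            raise ValueError("missing HbA1c")
        for lab in ("hba1c",) + OPTIONAL_LABS:
            v = getattr(self, lab)
            if v is not None and np.isfinite(v) and v < 0:
                raise ValueError(f"negative {lab}: {v}")
        self.baseline_profile.validate()
        if self.followup_profile is not None:
            self.followup_profile.validate()
            if self.followup_interval is not None and self.followup_interval < 6:
                raise ValueError(
                    f"follow-up interval {self.followup_interval} months < 6"
                )

    @property
    def has_followup(self) -> bool:
        return self.followup_profile is not None


@dataclass
class CohortReadResult:
    records: list[ParticipantRecord]
    rejects: list[tuple[int, str]]  # (row index, reason)


def _profile_cols(prefix: str = "") -> list[str]:
    return [f"{prefix}{a}_{t}" for a in ("glucose", "insulin")
            for t in TIME_SUFFIXES]


WIDE_REQUIRED = ["id", "age", "sex", "race", "ethnicity", "bmi_percentile",
                 "hba1c"] + _profile_cols()


def _get(row, col):
    v = row.get(col)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def _row_to_record(row: pd.Series) -> ParticipantRecord:
    def series(prefix, analyte):
        vals = []
        for t in TIME_SUFFIXES:
            v = row.get(f"{prefix}{analyte}_{t}", np.nan)
            vals.append(np.nan if v is None else float(v))
        arr = np.array(vals, float)
        return arr[np.isfinite(arr)] if not np.all(np.isfinite(arr)) else arr

    baseline = OGTTProfile(series("", "glucose"), series("", "insulin"))
    followup = None
    fu_g = series("followup_", "glucose")
    fu_i = series("followup_", "insulin")
    if fu_g.size or fu_i.size:
        followup = OGTTProfile(fu_g, fu_i)
    interval = _get(row, "followup_interval")
    rec = ParticipantRecord(
        id=str(row["id"]),
        age=float(row["age"]),
        sex=str(row["sex"]),
        race=str(row["race"]),
        ethnicity=str(row["ethnicity"]),
        bmi_percentile=float(row["bmi_percentile"]),
        hba1c=(float(row["hba1c"]) if _get(row, "hba1c") is not None else np.nan),
        baseline_profile=baseline,
        followup_profile=followup,
        followup_interval=(float(interval) if interval is not None else None),
    )
    for lab in OPTIONAL_LABS:
        v = _get(row, lab)
        setattr(rec, lab, float(v) if v is not None else None)
    return rec


def read_cohort(path: str | Path, schema: str = "wide") -> CohortReadResult:
    """Read and validate a cohort table; invalid rows become rejects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if schema == "long":
        df = _long_to_wide(df)
    elif schema != "wide":
        raise ValueError(f"unknown schema {schema!r}")
    missing = [c for c in WIDE_REQUIRED if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    if df.empty:
        logger.warning("cohort file %s contains a header but no rows", path)
        return CohortReadResult([], [])
    for col in _profile_cols():
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                           & df[col].notna()].tolist()
            if bad:
                raise ValueError(
                    f"non-numeric values in column {col!r} at rows {bad}"
                )
            df[col] = pd.to_numeric(df[col], errors="coerce")
    records, rejects = [], []
    for idx, row in df.iterrows():
        try:
            rec = _row_to_record(row)
            rec.validate()
            records.append(rec)
        except (ValueError, KeyError) as exc:
            rejects.append((int(idx), str(exc)))
    for idx, reason in rejects:
        logger.info("row %d excluded: %s", idx, reason)
    return CohortReadResult(records, rejects)


def _long_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    need = {"id", "time", "glucose", "insulin"}
    missing = sorted(need - set(df.columns))
    if missing:
        raise CohortSchemaError(f"missing required column(s): {missing}")
    demo_cols = [c for c in df.columns if c not in ("time", "glucose", "insulin")]
    demo = df[demo_cols].groupby("id", sort=False).first().reset_index()
    wide = df.pivot_table(index="id", columns="time",
                          values=["glucose", "insulin"], aggfunc="first")
    wide.columns = [f"{a}_{int(t)}" for a, t in wide.columns]
    return demo.merge(wide.reset_index(), on="id")


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Flatten records into the wide cohort dialect."""
    rows = []
    for r in records:
        row = {f.name: getattr(r, f.name) for f in fields(r)
               if f.name not in ("baseline_profile", "followup_profile")}
        for t, g, i in zip(TIME_SUFFIXES, r.baseline_profile.glucose,
                           r.baseline_profile.insulin):
            row[f"glucose_{t}"] = g
            row[f"insulin_{t}"] = i
        if r.followup_profile is not None:
            for t, g, i in zip(TIME_SUFFIXES, r.followup_profile.glucose,
                               r.followup_profile.insulin):
                row[f"followup_glucose_{t}"] = g
                row[f"followup_insulin_{t}"] = i
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(records: list[ParticipantRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False, na_rep="")


def write_results(
    tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write one CSV per table plus a run manifest (config hash + seed).

    Missing values are serialized as empty fields.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname, index=False, na_rep="")
        files[name] = fname
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    manifest = {
        "files": files,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
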