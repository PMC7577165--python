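"""Data model and I/O for NONMEM-dialect PK/PD trial datasets.

The on-disk dialect is a long-format CSV with one row per dose event or
concentration observation:

========  =======================================================
column    meaning
========  =======================================================
ID        subject identifier (string)
TIME      hours since first dose (non-decreasing within a subject)
TAD       hours since most recent dose (optional; derivable)
AMT       dose amount in nmol (dose events only)
DV        plasma concentration in nM (observations only)
EVID      0 = observation, 1 = dose event
MDV       1 = DV missing / not usable for fitting
WT        body weight, kg
AGE       age, years
STAT      infection status: ``healthy`` or ``hiv``
GRP       treatment group: ``ISG``, ``DSG`` or ``naive``
========  =======================================================

Missing values are empty strings or ``.``.  Concentrations are stored in nM
and dose amounts in nmol so that AUC emerges in nM*h without unit juggling;
the drug's molecular weight (config constant) converts a mg dose to nmol.

Rows at the same TIME keep file order; an observation row written before a
dose row at the same time is a predose sample.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DatasetFormatError",
    "PKRecord",
    "Subject",
    "DosingRegimen",
    "AnalysisConfig",
    "ValidationReport",
    "read_pk_dataset",
    "write_pk_dataset",
    "read_efficacy",
    "write_efficacy",
    "validate_dataset",
    "dose_to_amount",
    "derive_time_after_dose",
    "load_analysis_config",
]

STATUSES = ("healthy", "hiv")
GROUPS = ("ISG", "DSG", "naive")

MANDATORY_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "WT", "AGE", "STAT", "GRP"]


class DatasetFormatError(ValueError):
    """Raised when a dataset file violates the documented CSV dialect."""


@dataclass
class PKRecord:
    subject_id: str
    time: float
    amt: float = 0.0
    dv: float | None = None
    evid: int = 0
    mdv: int = 0
    time_after_dose: float | None = None

    @property
    def is_dose(self) -> bool:
        return self.evid == 1

    @property
    def usable_for_fitting(self) -> bool:
        """Observation rows with a non-missing DV enter the likelihood."""
        return self.evid == 0 and self.mdv == 0 and self.dv is not None


@dataclass(frozen=True)
class Subject:
    subject_id: str
    weight: float
    age: float
    status: str = "hiv"
    group: str = "ISG"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not (np.isfinite(self.weight) and self.weight > 0):
            raise ValueError(f"subject {self.subject_id}: weight must be finite and > 0")
        if not (np.isfinite(self.age) and self.age > 0):
            raise ValueError(f"subject {self.subject_id}: age must be finite and > 0")


@dataclass(frozen=True)
class DosingRegimen:
    """Repeated oral dosing: `dose_mg` every `tau` hours.

    `molecular_weight` (g/mol) converts the mg dose to nmol so that
    concentrations computed from it are in nM.  The default is doravirine's
    molecular weight; it is a configuration constant, not an estimate.
    """

    dose_mg: float = 100.0
    tau: float = 24.0
    molecular_weight: float = 425.75

    def __post_init__(self) -> None:
        if not (self.dose_mg > 0 and self.tau > 0 and self.molecular_weight > 0):
            raise ValueError("dose_mg, tau and molecular_weight must all be positive")

    @property
    def amount_nmol(self) -> float:
        return dose_to_amount(self)


def dose_to_amount(regimen: DosingRegimen) -> float:
    """Dose amount in nmol: dose_mg / molecular_weight * 1e6."""
    if regimen.dose_mg <= 0 or regimen.molecular_weight <= 0:
        raise ValueError("dose and molecular weight must be positive")
    return regimen.dose_mg / regimen.molecular_weight * 1e6


@dataclass
class AnalysisConfig:
    """Run-wide constants: regimen, covariate reference values, tolerances."""

    regimen: DosingRegimen = field(default_factory=DosingRegimen)
    weight_ref: float = 70.0
    age_ref: float = 45.0
    thresholds: tuple[int, ...] = (50, 40)
    seed: int = 20240
    inner_tol: float = 1e-10
    outer_tol: float = 1e-8
    percentile_method: str = "linear"

    def __post_init__(self) -> None:
        if self.weight_ref <= 0 or self.age_ref <= 0:
            raise ValueError("covariate reference values must be positive")
        for thr in self.thresholds:
            if thr <= 0:
                raise ValueError("endpoint thresholds must be positive")


def load_analysis_config(path: str) -> AnalysisConfig:
    """Build an AnalysisConfig from the `analysis:` section of a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    section = raw.get("analysis", raw)
    reg = DosingRegimen(**section.pop("regimen", {}))
    if "thresholds" in section:
        section["thresholds"] = tuple(section["thresholds"])
    return AnalysisConfig(regimen=reg, **section)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_NA = ("", ".")


def _numeric(df: pd.DataFrame, col: str, path: str) -> pd.Series:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() & ~raw.astype(str).str.strip().isin(_NA)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise DatasetFormatError(
            f"{path}: non-numeric value {raw[bad.idxmax()]!r} in column {col} at line {line}"
        )
    return out


def read_pk_dataset(
    path: str, config: AnalysisConfig | None = None
) -> tuple[list[PKRecord], list[Subject]]:
    """Read a long-format PK dataset; returns (records, subjects).

    Row order is preserved; subjects are deduplicated in order of first
    appearance.  Extra columns are ignored.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=list(_NA))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    time = _numeric(df, "TIME", path)
    amt = _numeric(df, "AMT", path).fillna(0.0)
    dv = _numeric(df, "DV", path)
    evid = _numeric(df, "EVID", path).fillna(0).astype(int)
    mdv = _numeric(df, "MDV", path).fillna(0).astype(int)
    tad = _numeric(df, "TAD", path) if "TAD" in df.columns else pd.Series(np.nan, index=df.index)
    wt = _numeric(df, "WT", path)
    age = _numeric(df, "AGE", path)

    records: list[PKRecord] = []
    for i in range(len(df)):
        records.append(
            PKRecord(
                subject_id=str(df["ID"].iloc[i]),
                time=float(time.iloc[i]),
                amt=float(amt.iloc[i]),
                dv=None if pd.isna(dv.iloc[i]) else float(dv.iloc[i]),
                evid=int(evid.iloc[i]),
                mdv=int(mdv.iloc[i]),
                time_after_dose=None if pd.isna(tad.iloc[i]) else float(tad.iloc[i]),
            )
        )

    subjects: list[Subject] = []
    seen: set[str] = set()
    for i in range(len(df)):
        sid = str(df["ID"].iloc[i])
        if sid in seen:
            continue
        seen.add(sid)
        subjects.append(
            Subject(
                subject_id=sid,
                weight=float(wt.iloc[i]),
                age=float(age.iloc[i]),
                status=str(df["STAT"].iloc[i]).strip().lower(),
                group=str(df["GRP"].iloc[i]).strip(),
            )
        )
    return records, subjects


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return format(float(x), ".17g")


def write_pk_dataset(records: Sequence[PKRecord], subjects: Sequence[Subject], path: str) -> None:
    """Write the dataset in the documented dialect (round-trips with read)."""
    cov = {s.subject_id: s for s in subjects}
    buf = io.StringIO()
    buf.write(",".join(MANDATORY_COLUMNS[:3] + ["TAD"] + MANDATORY_COLUMNS[3:]) + "\n")
    # header order: ID,TIME,AMT,TAD,DV,EVID,MDV,WT,AGE,STAT,GRP
    for r in records:
        s = cov[r.subject_id]
        buf.write(
            ",".join(
                [
                    r.subject_id,
                    _fmt(r.time),
                    _fmt(r.amt),
                    _fmt(r.time_after_dose),
                    _fmt(r.dv),
                    str(r.evid),
                    str(r.mdv),
                    _fmt(s.weight),
                    _fmt(s.age),
                    s.status,
                    s.group,
                ]
            )
            + "\n"
        )
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


@dataclass
class EfficacyRecord:
    """Per-subject week-48 virologic outcome.

    `week48_rna` is the HIV-1 RNA level (copies/ml) at week 48, or None when
    the measurement is missing; `disc_reason` records why a subject with a
    missing value discontinued ('lack_of_efficacy', 'other', or 'none').
    """

    subject_id: str
    week48_rna: float | None = None
    disc_reason: str = "none"
    disc_week: float | None = None

    def __post_init__(self) -> None:
        if self.disc_reason not in ("none", "lack_of_efficacy", "other"):
            raise ValueError(f"invalid disc_reason {self.disc_reason!r}")
        if self.week48_rna is not None and self.week48_rna < 0:
            raise ValueError("week48_rna must be >= 0")
        if self.disc_week is not None and self.disc_week > 48:
            raise ValueError("disc_week must be <= 48")


def write_efficacy(records: Sequence[EfficacyRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("ID,WEEK48_RNA,DISC_REASON,DISC_WEEK\n")
        for r in records:
            fh.write(f"{r.subject_id},{_fmt(r.week48_rna)},{r.disc_reason},{_fmt(r.disc_week)}\n")


def read_efficacy(path: str) -> list[EfficacyRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=list(_NA))
    for col in ("ID", "WEEK48_RNA", "DISC_REASON", "DISC_WEEK"):
        if col not in df.columns:
            raise DatasetFormatError(f"{path}: missing mandatory column(s): {col}")
    rna = _numeric(df, "WEEK48_RNA", path)
    week = _numeric(df, "DISC_WEEK", path)
    out = []
    for i in range(len(df)):
        out.append(
            EfficacyRecord(
                subject_id=str(df["ID"].iloc[i]),
                week48_rna=None if pd.isna(rna.iloc[i]) else float(rna.iloc[i]),
                disc_reason=str(df["DISC_REASON"].iloc[i]).strip() or "none",
                disc_week=None if pd.isna(week.iloc[i]) else float(week.iloc[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_dataset(
    records: Sequence[PKRecord], subjects: Sequence[Subject]
) -> ValidationReport:
    """Report-only check of record and subject invariants."""
    rep = ValidationReport()
    known = set()
    for s in subjects:
        if s.subject_id in known:
            rep.violations.append(f"subject {s.subject_id}: duplicate subject_id")
        known.add(s.subject_id)
        if not (np.isfinite(s.weight) and s.weight > 0):
            rep.violations.append(f"subject {s.subject_id}: weight must be finite and > 0")
        if not (np.isfinite(s.age) and s.age > 0):
            rep.violations.append(f"subject {s.subject_id}: age must be finite and > 0")

    last_time: dict[str, float] = {}
    for i, r in enumerate(records):
        where = f"row {i} (subject {r.subject_id})"
        if r.subject_id not in known:
            rep.violations.append(f"{where}: unknown subject")
        if r.evid == 1:
            if not r.amt > 0:
                rep.violations.append(f"{where}: dose event with amt <= 0")
            if r.mdv != 1:
                rep.violations.append(f"{where}: dose event must have mdv = 1")
        elif r.evid == 0:
            if r.amt not in (0.0, None) and r.amt != 0:
                rep.violations.append(f"{where}: observation with amt > 0")
            if r.dv is not None and r.dv < 0:
                rep.violations.append(f"{where}: dv < 0")
        else:
            rep.violations.append(f"{where}: unknown evid {r.evid}")
        if r.time < 0:
            rep.violations.append(f"{where}: negative time")
        prev = last_time.get(r.subject_id)
        if prev is not None and r.time < prev:
            rep.violations.append(f"{where}: time decreases within subject")
        last_time[r.subject_id] = r.time
    return rep


def derive_time_after_dose(records: Iterable[PKRecord]) -> list[PKRecord]:
    """Fill `time_after_dose` from the most recent prior dose row (file order).

    Observations before any dose keep time_after_dose=None.
    """
    out: list[PKRecord] = []
    last_dose: dict[str, float] = {}
    for r in records:
        if r.is_dose:
            last_dose[r.subject_id] = r.time
            out.append(replace(r))
            continue
        if r.time_after_dose is None and r.subject_id in last_dose:
            out.append(replace(r, time_after_dose=r.time - last_dose[r.subject_id]))
        else:
            out.append(replace(r))
    return out
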