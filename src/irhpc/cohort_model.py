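"""Domain types, tabular IO and validation for a neoadjuvant study cohort.

Two tables are understood:

``patients`` — one row per (case, rater): pretreatment biopsy feature
grades, per-rater tumour-bed component areas from the resection, the
recorded immune-activated %RVT, and per-case blood counts and survival
fields (repeated on every rater row of the case).

``pdl1`` — one row per case from the independent PD-L1 series: viable
tumour-cell count on the IHC slide, tumour proportion score, and whether
eosinophils appear in both the tumour parenchyma and the stroma.

All files are plain UTF-8 CSV with a header row ("." decimal mark);
``.json`` paths use a records-orientation JSON of the same columns.
Missing values are empty cells and stay ``NaN``/``None`` in memory —
nothing is imputed here; downstream operations decide per-op how to
treat missingness.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

ORDINAL_GRADES = (0, 1, 2, 3)

PATIENT_COLUMNS = [
    "case_id",
    "rater_id",
    "til_grade",
    "eos_grade",
    "neut_grade",
    "dense_plasma",
    "rvt_area",
    "necrosis_area",
    "regression_area",
    "immune_activated_rvt_pct",
    "neutrophil_count",
    "leukocyte_count",
    "dfs_months",
    "dfs_event",
    "os_months",
    "os_event",
    "death_unrelated",
]

PDL1_COLUMNS = [
    "case_id",
    "viable_tumour_cells",
    "tps_percent",
    "eos_both_compartments",
]

_SCHEMAS = {"patients": PATIENT_COLUMNS, "pdl1": PDL1_COLUMNS}


class CohortError(ValueError):
    """Raised when a cohort file cannot be accepted at all (missing file,
    missing or unknown columns)."""


@dataclass(frozen=True)
class Violation:
    """One validation failure: which record, which field, which rule."""

    where: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.where}: {self.field}: {self.message}"


@dataclass(frozen=True)
class FeatureGrades:
    """The four pretreatment biopsy features entering the irHPC score.

    TILs, eosinophils and neutrophils are ordinal 0/1+/2+/3+ grades
    (encoded 0..3); dense plasma cells in the tumour-related stroma are
    recorded as present/absent.
    """

    til: int
    eosinophils: int
    neutrophils: int
    dense_plasma_cells: bool

    def validate(self, where: str = "FeatureGrades") -> list[Violation]:
        out = []
        for name in ("til", "eosinophils", "neutrophils"):
            v = getattr(self, name)
            if v not in ORDINAL_GRADES:
                out.append(Violation(where, name, f"ordinal grade {v!r} not in {{0,1,2,3}}"))
        if self.dense_plasma_cells not in (True, False, 0, 1):
            out.append(Violation(where, "dense_plasma_cells", "must be binary present/absent"))
        return out


@dataclass(frozen=True)
class TumourBedAreas:
    """Residual viable tumour, necrosis and regression-bed areas summed
    across all slides of a case (arbitrary but mutually consistent units)."""

    rvt_area: float
    necrosis_area: float
    regression_area: float

    @property
    def tumour_bed(self) -> float:
        return self.rvt_area + self.necrosis_area + self.regression_area

    def validate(self, where: str = "TumourBedAreas") -> list[Violation]:
        out = []
        for name in ("rvt_area", "necrosis_area", "regression_area"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                out.append(Violation(where, name, f"area must be finite and >= 0, got {v!r}"))
        if not out and self.tumour_bed <= 0:
            out.append(Violation(where, "tumour_bed", "tumour bed empty (all component areas zero)"))
        return out


@dataclass(frozen=True)
class BloodCount:
    """Pretreatment absolute neutrophil and leukocyte counts (10^9/L)."""

    neutrophils: float
    leukocytes: float

    def validate(self, where: str = "BloodCount") -> list[Violation]:
        out = []
        if not (self.neutrophils > 0):
            out.append(Violation(where, "neutrophils", "count must be > 0"))
        if not (self.leukocytes > self.neutrophils):
            out.append(Violation(where, "leukocytes", "leukocytes must exceed neutrophils"))
        return out


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored DFS/OS follow-up in months.

    ``death_unrelated_to_treatment`` marks deaths excluded from the
    survival analysis set; it is only meaningful when ``os_event`` is 1.
    """

    dfs_time: float
    dfs_event: int
    os_time: float
    os_event: int
    death_unrelated_to_treatment: int = 0

    def validate(self, where: str = "SurvivalRecord") -> list[Violation]:
        out = []
        if not (self.dfs_time >= 0):
            out.append(Violation(where, "dfs_time", "time must be >= 0"))
        if not (self.os_time >= 0):
            out.append(Violation(where, "os_time", "time must be >= 0"))
        for name in ("dfs_event", "os_event", "death_unrelated_to_treatment"):
            if getattr(self, name) not in (0, 1):
                out.append(Violation(where, name, "flag must be 0/1"))
        if self.death_unrelated_to_treatment == 1 and self.os_event != 1:
            out.append(Violation(where, "death_unrelated_to_treatment",
                                 "flag set without an observed death"))
        return out


@dataclass(frozen=True)
class Pdl1Record:
    """One case of the PD-L1 series: viable tumour-cell count on the IHC
    slide, tumour proportion score, and the eosinophil compartment flag."""

    case_id: str
    viable_tumour_cells: int
    tps: float
    eosinophils_both_compartments: bool

    def validate(self, where: str | None = None) -> list[Violation]:
        where = where or f"pdl1[{self.case_id}]"
        out = []
        if self.viable_tumour_cells < 0:
            out.append(Violation(where, "viable_tumour_cells", "count must be >= 0"))
        if not (0 <= self.tps <= 100):
            out.append(Violation(where, "tps", f"TPS must lie in [0,100], got {self.tps!r}"))
        return out


@dataclass
class PatientRecord:
    """One neoadjuvant patient, keyed by case_id.

    Per-rater dictionaries hold the pretreatment biopsy grades and the
    resection areas; cases without an eligible paired biopsy simply have
    an empty ``grades`` dict.
    """

    case_id: str
    grades: dict[str, FeatureGrades] = field(default_factory=dict)
    areas: dict[str, TumourBedAreas] = field(default_factory=dict)
    immune_activated_rvt_pct: dict[str, float] = field(default_factory=dict)
    blood: BloodCount | None = None
    survival: SurvivalRecord | None = None
    response: str | None = None


def validate_record(record: PatientRecord) -> list[Violation]:
    """Check every type invariant of a patient record.

    Violations are data, not exceptions: an empty list means the record
    is fully valid.
    """
    out: list[Violation] = []
    cid = record.case_id
    for rater, g in record.grades.items():
        out.extend(g.validate(f"{cid}/{rater}"))
    for rater, a in record.areas.items():
        out.extend(a.validate(f"{cid}/{rater}"))
    for rater, pct in record.immune_activated_rvt_pct.items():
        if pct is not None and not (0 <= pct <= 100):
            out.append(Violation(f"{cid}/{rater}", "immune_activated_rvt_pct",
                                 f"percent must lie in [0,100], got {pct!r}"))
    if record.blood is not None:
        out.extend(record.blood.validate(f"{cid}"))
    if record.survival is not None:
        out.extend(record.survival.validate(f"{cid}"))
    return out


# ---------------------------------------------------------------------------
# tabular IO


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise CohortError(f"no such cohort file: {path}")
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path)


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    unknown = [c for c in df.columns if c not in expected]
    if missing:
        raise CohortError(f"{path}: missing required columns {missing}")
    if unknown:
        raise CohortError(f"{path}: unknown columns {unknown}")


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or (
        isinstance(v, str) and v.strip() == "")


def _validate_patient_row(i: int, row: pd.Series) -> list[Violation]:
    where = f"row {i} (case {row['case_id']})"
    out: list[Violation] = []
    for col in ("til_grade", "eos_grade", "neut_grade"):
        v = row[col]
        if not _is_missing(v) and v not in ORDINAL_GRADES:
            out.append(Violation(where, col, f"ordinal grade {v!r} not in {{0,1,2,3}}"))
    for col in ("dense_plasma", "dfs_event", "os_event", "death_unrelated"):
        v = row[col]
        if not _is_missing(v) and v not in (0, 1):
            out.append(Violation(where, col, f"flag must be 0/1, got {v!r}"))
    for col in ("rvt_area", "necrosis_area", "regression_area", "dfs_months", "os_months"):
        v = row[col]
        if not _is_missing(v) and v < 0:
            out.append(Violation(where, col, f"must be >= 0, got {v!r}"))
    v = row["immune_activated_rvt_pct"]
    if not _is_missing(v) and not (0 <= v <= 100):
        out.append(Violation(where, "immune_activated_rvt_pct", f"percent outside [0,100]: {v!r}"))
    n, l = row["neutrophil_count"], row["leukocyte_count"]
    if not _is_missing(n) and n <= 0:
        out.append(Violation(where, "neutrophil_count", f"count must be > 0, got {n!r}"))
    if not _is_missing(n) and not _is_missing(l) and l <= n:
        out.append(Violation(where, "leukocyte_count", "leukocytes must exceed neutrophils"))
    return out


def _validate_pdl1_row(i: int, row: pd.Series) -> list[Violation]:
    where = f"row {i} (case {row['case_id']})"
    out: list[Violation] = []
    if row["viable_tumour_cells"] < 0:
        out.append(Violation(where, "viable_tumour_cells", "count must be >= 0"))
    if not (0 <= row["tps_percent"] <= 100):
        out.append(Violation(where, "tps_percent", f"TPS outside [0,100]: {row['tps_percent']!r}"))
    if row["eos_both_compartments"] not in (0, 1):
        out.append(Violation(where, "eos_both_compartments", "flag must be 0/1"))
    return out


def read_cohort(path: str | Path, table_kind: str = "patients"
                ) -> tuple[pd.DataFrame, list[Violation]]:
    """Read and validate a cohort table.

    Returns the parsed frame (all rows, including ones that carry
    violations) together with the per-row violation list. Files with
    missing or unknown columns are rejected outright with CohortError.
    """
    if table_kind not in _SCHEMAS:
        raise ValueError(f"unknown table_kind {table_kind!r}; expected one of {sorted(_SCHEMAS)}")
    df = _read_frame(path)
    if df.empty and list(df.columns) == []:
        # header-only CSV parses to zero columns via json; normalise
        df = pd.DataFrame(columns=_SCHEMAS[table_kind])
    _check_columns(df, _SCHEMAS[table_kind], path)
    df = df[_SCHEMAS[table_kind]].copy()
    check = _validate_patient_row if table_kind == "patients" else _validate_pdl1_row
    violations: list[Violation] = []
    for i, row in df.iterrows():
        violations.extend(check(int(i), row))
    return df, violations


def write_cohort(cohort: pd.DataFrame, path: str | Path, table_kind: str = "patients") -> None:
    """Serialise a cohort frame with a deterministic column order.

    The output is readable back by :func:`read_cohort` with the same
    ``table_kind``; an empty cohort yields a header-only file.
    """
    cols = _SCHEMAS[table_kind]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise CohortError(f"cohort frame lacks columns {missing}")
    out = cohort[cols]
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(out.to_dict(orient="records"), indent=1, default=float),
                        encoding="utf-8")
    else:
        out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# frame <-> record conversion


def _opt(v, cast=float):
    return None if _is_missing(v) else cast(v)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    """Group a patients frame (one row per case/rater) into PatientRecords.

    Per-case fields (blood counts, survival) are taken from the first
    row of each case; grades and areas are collected per rater and
    omitted for raters whose cells are empty.
    """
    records: list[PatientRecord] = []
    for case_id, grp in df.groupby("case_id", sort=False):
        first = grp.iloc[0]
        rec = PatientRecord(case_id=str(case_id))
        for _, row in grp.iterrows():
            rater = str(row["rater_id"])
            if not any(_is_missing(row[c]) for c in ("til_grade", "eos_grade", "neut_grade",
                                                     "dense_plasma")):
                rec.grades[rater] = FeatureGrades(
                    til=int(row["til_grade"]), eosinophils=int(row["eos_grade"]),
                    neutrophils=int(row["neut_grade"]),
                    dense_plasma_cells=bool(row["dense_plasma"]))
            if not any(_is_missing(row[c]) for c in ("rvt_area", "necrosis_area",
                                                     "regression_area")):
                rec.areas[rater] = TumourBedAreas(
                    rvt_area=float(row["rvt_area"]), necrosis_area=float(row["necrosis_area"]),
                    regression_area=float(row["regression_area"]))
            if not _is_missing(row["immune_activated_rvt_pct"]):
                rec.immune_activated_rvt_pct[rater] = float(row["immune_activated_rvt_pct"])
        if not _is_missing(first["neutrophil_count"]) and not _is_missing(first["leukocyte_count"]):
            rec.blood = BloodCount(float(first["neutrophil_count"]),
                                   float(first["leukocyte_count"]))
        if not _is_missing(first["dfs_months"]) and not _is_missing(first["os_months"]):
            rec.survival = SurvivalRecord(
                dfs_time=float(first["dfs_months"]), dfs_event=int(first["dfs_event"]),
                os_time=float(first["os_months"]), os_event=int(first["os_event"]),
                death_unrelated_to_treatment=int(first["death_unrelated"])
                if not _is_missing(first["death_unrelated"]) else 0)
        records.append(rec)
    return records


def pdl1_records_from_frame(df: pd.DataFrame) -> list[Pdl1Record]:
    return [
        Pdl1Record(case_id=str(r["case_id"]),
                   viable_tumour_cells=int(r["viable_tumour_cells"]),
                   tps=float(r["tps_percent"]),
                   eosinophils_both_compartments=bool(r["eos_both_compartments"]))
        for _, r in df.iterrows()
    ]
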