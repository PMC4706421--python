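"""Subjects, cohorts and tabular I/O.

A :class:`Subject` is one person's demographics, anthropometrics, blood
pressure, fasting labs and history flags, in fixed units (cm, kg, mmHg,
mmol/L, mIU/L, years).  Missingness is explicit: any measurement may be
``None`` and downstream scores propagate that missingness instead of
imputing.  A :class:`Cohort` is an ordered collection of subjects with
unique identifiers.

CSV (and single-sheet XLSX) ingestion is deliberately forgiving about
column *names* — clinical exports are inconsistent, so a case-insensitive
alias map translates common variants — but strict about *units*: there is
no auto-conversion, and values that can only be conventional mg/dL (e.g.
fasting glucose above 30) raise :class:`UnitError` rather than silently
producing garbage scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A mandatory column is absent or the header is unusable."""


class CohortIntegrityError(ValueError):
    """Duplicate subject identifiers or similar structural violations."""


class UnitError(ValueError):
    """A value is implausible in the fixed unit system (likely mg/dL input)."""


MALE = "male"
FEMALE = "female"

_SEX_MAP = {
    "m": MALE, "male": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
}

_BOOL_MAP = {
    "1": True, "true": True, "yes": True, "y": True, "+": True, "t": True,
    "0": False, "false": False, "no": False, "n": False, "-": False,
    "": None,
}

#: numeric measurement fields, in canonical order
NUMERIC_FIELDS = (
    "age", "height", "weight", "waist", "systolic_bp", "diastolic_bp",
    "glucose", "insulin", "triglycerides", "hdl",
)

BOOL_FIELDS = (
    "family_history_cv", "treated_lipids", "treated_bp",
    "treated_glucose", "treated_hdl",
)

#: case-insensitive header aliases -> canonical field names
COLUMN_ALIASES: dict[str, str] = {
    "id": "subject_id", "subject": "subject_id", "patient_id": "subject_id",
    "patient": "subject_id",
    "gender": "sex",
    "age_years": "age",
    "height_cm": "height", "body_height": "height",
    "weight_kg": "weight", "body_weight": "weight",
    "waist_circumference": "waist", "wc": "waist", "waist_cm": "waist",
    "sbp": "systolic_bp", "ta_systolic": "systolic_bp",
    "systolic": "systolic_bp", "sys_bp": "systolic_bp",
    "dbp": "diastolic_bp", "ta_diastolic": "diastolic_bp",
    "diastolic": "diastolic_bp", "dia_bp": "diastolic_bp",
    "gly": "glucose", "glu": "glucose", "fasting_glucose": "glucose",
    "glucose_0": "glucose",
    "ins": "insulin", "fasting_insulin": "insulin", "insulin_0": "insulin",
    "tg": "triglycerides", "trig": "triglycerides", "tgl": "triglycerides",
    "hdl_cholesterol": "hdl", "hdl_c": "hdl",
    "family_history": "family_history_cv", "fh_cv": "family_history_cv",
    "heredity": "family_history_cv",
    "treated_tg": "treated_lipids", "lipid_treatment": "treated_lipids",
    "bp_treatment": "treated_bp", "antihypertensives": "treated_bp",
    "glucose_treatment": "treated_glucose",
    "hdl_treatment": "treated_hdl",
}

#: plausibility ceilings in the fixed units; above them the value can only
#: be a conventional-unit (mg/dL) export
_UNIT_CEILINGS = {"glucose": 30.0, "triglycerides": 40.0, "hdl": 10.0}


@dataclass
class Subject:
    """One study participant.

    Units: height/waist in cm, weight in kg, blood pressure in mmHg,
    glucose / triglycerides / HDL in mmol/L, insulin in mIU/L, age in
    years.  Treatment flags default to ``False`` (known negative);
    ``family_history_cv`` defaults to ``None`` (unknown).
    """

    subject_id: str
    sex: str
    age: Optional[float] = None
    height: Optional[float] = None
    weight: Optional[float] = None
    waist: Optional[float] = None
    systolic_bp: Optional[float] = None
    diastolic_bp: Optional[float] = None
    glucose: Optional[float] = None
    insulin: Optional[float] = None
    triglycerides: Optional[float] = None
    hdl: Optional[float] = None
    family_history_cv: Optional[bool] = None
    treated_lipids: bool = False
    treated_bp: bool = False
    treated_glucose: bool = False
    treated_hdl: bool = False

    def __post_init__(self) -> None:
        if self.sex not in (MALE, FEMALE):
            self.sex = parse_sex(self.sex)
        for name in NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is not None:
                if not math.isfinite(v) or v <= 0:
                    raise ValueError(
                        f"subject {self.subject_id!r}: {name} must be a "
                        f"positive finite number, got {v!r}"
                    )
        if (
            self.systolic_bp is not None
            and self.diastolic_bp is not None
            and self.systolic_bp <= self.diastolic_bp
        ):
            raise ValueError(
                f"subject {self.subject_id!r}: systolic_bp must exceed "
                f"diastolic_bp ({self.systolic_bp} <= {self.diastolic_bp})"
            )

    def has(self, *names: str) -> bool:
        """True if every named field is present (not None)."""
        return all(getattr(self, n) is not None for n in names)


def parse_sex(value) -> str:
    key = str(value).strip().lower()
    try:
        return _SEX_MAP[key]
    except KeyError:
        raise ValueError(f"unrecognised sex code {value!r} "
                         f"(accepted: m/f/male/female/1/2)") from None


def parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key in _BOOL_MAP:
        return _BOOL_MAP[key]
    raise ValueError(f"unrecognised boolean code {value!r}")


class Cohort:
    """Ordered collection of subjects with unique identifiers."""

    def __init__(self, subjects: Iterable[Subject], provenance: str = ""):
        self.subjects: list[Subject] = list(subjects)
        self.provenance = provenance
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortIntegrityError(f"duplicate subject_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[Subject]:
        return iter(self.subjects)

    def __getitem__(self, i):
        return self.subjects[i]

    def to_dataframe(self) -> pd.DataFrame:
        """One row per subject, canonical column order, NaN for missing."""
        cols = [f.name for f in dc_fields(Subject)]
        rows = [{c: getattr(s, c) for c in cols} for s in self.subjects]
        df = pd.DataFrame(rows, columns=cols)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "",
                       lenient: bool = True) -> "Cohort":
        """Build a cohort from a canonical-column DataFrame.

        With ``lenient=True`` (the ingestion default) cells that violate a
        subject-level invariant are demoted to missing with a logged
        warning; with ``lenient=False`` they raise.
        """
        subjects = []
        for _, row in df.iterrows():
            kw = _row_to_kwargs(row)
            if lenient:
                subjects.append(_build_lenient(kw))
            else:
                subjects.append(Subject(**kw))
        return cls(subjects, provenance=provenance)


def _row_to_kwargs(row: pd.Series) -> dict:
    kw: dict = {"subject_id": str(row["subject_id"]), "sex": row["sex"]}
    for name in NUMERIC_FIELDS:
        if name in row.index:
            v = row[name]
            kw[name] = None if pd.isna(v) else float(v)
    for name in BOOL_FIELDS:
        if name in row.index:
            v = parse_bool(row[name]) if not isinstance(row[name], (bool, np.bool_)) else bool(row[name])
            if name == "family_history_cv":
                kw[name] = v
            else:
                kw[name] = bool(v) if v is not None else False
    return kw


def _build_lenient(kw: dict) -> Subject:
    """Construct a Subject, demoting invariant-violating cells to missing."""
    for attempt in range(len(NUMERIC_FIELDS) + 2):
        try:
            return Subject(**kw)
        except ValueError as exc:
            msg = str(exc)
            if "systolic_bp must exceed" in msg:
                logger.warning("%s; dropping both pressures", msg)
                kw["systolic_bp"] = kw["diastolic_bp"] = None
                continue
            dropped = False
            for name in NUMERIC_FIELDS:
                if f" {name} must be" in msg:
                    logger.warning("%s; treating as missing", msg)
                    kw[name] = None
                    dropped = True
                    break
            if not dropped:
                raise
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# reading


def read_cohort(path: str | Path, dialect: str | None = None) -> Cohort:
    """Read a cohort from CSV or single-sheet XLSX.

    The header is matched case-insensitively against the canonical field
    names and :data:`COLUMN_ALIASES`.  ``subject_id``, ``sex`` and ``age``
    are mandatory.  Unparseable cells become missing values with a logged
    warning; implausible unit-system values raise :class:`UnitError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if dialect == "xlsx":
        raw = pd.read_excel(path, dtype=object)
    elif dialect == "csv":
        raw = pd.read_csv(path, dtype=object, skip_blank_lines=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    rename = {}
    for col in raw.columns:
        key = str(col).strip().lower()
        canonical = COLUMN_ALIASES.get(key, key)
        rename[col] = canonical
    raw = raw.rename(columns=rename)
    raw = raw.loc[:, ~raw.columns.duplicated()]

    missing = [c for c in ("subject_id", "sex", "age") if c not in raw.columns]
    if missing:
        raise SchemaError(f"mandatory column(s) missing: {', '.join(missing)}")

    df = pd.DataFrame(index=raw.index)
    df["subject_id"] = raw["subject_id"].astype(str).str.strip()
    df["sex"] = raw["sex"].map(_coerce_sex)
    for name in NUMERIC_FIELDS:
        if name in raw.columns:
            df[name] = raw[name].map(lambda v, n=name: _coerce_number(v, n))
    for name in BOOL_FIELDS:
        if name in raw.columns:
            df[name] = raw[name].map(_coerce_bool)

    for name, ceiling in _UNIT_CEILINGS.items():
        if name in df.columns:
            bad = df[name].dropna() > ceiling
            if bad.any():
                n_bad = int(bad.sum())
                raise UnitError(
                    f"column {name!r}: {n_bad} value(s) exceed {ceiling} — "
                    f"values must be mmol/L, not mg/dL"
                )

    if df["subject_id"].duplicated().any():
        dupes = sorted(df.loc[df["subject_id"].duplicated(), "subject_id"])
        raise CohortIntegrityError(f"duplicate subject_id(s): {dupes}")

    return Cohort.from_dataframe(df, provenance=str(path), lenient=True)


def _coerce_sex(value) -> str:
    return parse_sex(value)


def _coerce_number(value, name: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "null", "none", "."):
        return None
    try:
        return float(s)
    except ValueError:
        logger.warning("unparseable %s cell %r -> missing", name, value)
        return None


def _coerce_bool(value) -> Optional[bool]:
    try:
        return parse_bool(value)
    except ValueError:
        logger.warning("unparseable boolean cell %r -> missing", value)
        return None


# ---------------------------------------------------------------------------
# score tables


class ScoreTable:
    """Per-subject computed scores with explicit missingness accounting.

    Thin wrapper around a DataFrame whose first column is ``subject_id``;
    every other column is a score or derived measure with NaN marking
    "not computable for this subject".
    """

    def __init__(self, data: pd.DataFrame):
        if "subject_id" not in data.columns:
            raise ValueError("ScoreTable requires a subject_id column")
        self.data = data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    @property
    def columns(self) -> Sequence[str]:
        return list(self.data.columns)

    def counts(self) -> pd.Series:
        """Per-column count of subjects with a computed (non-missing) value."""
        return self.data.drop(columns=["subject_id"]).notna().sum()

    def equals(self, other: "ScoreTable", rtol: float = 1e-6) -> bool:
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if not (a["subject_id"].astype(str) == b["subject_id"].astype(str)).all():
            return False
        for col in a.columns[1:]:
            x = pd.to_numeric(a[col], errors="coerce").to_numpy(float)
            y = pd.to_numeric(b[col], errors="coerce").to_numpy(float)
            if not np.array_equal(np.isnan(x), np.isnan(y)):
                return False
            m = ~np.isnan(x)
            if m.any() and not np.allclose(x[m], y[m], rtol=rtol, atol=0):
                return False
        return True


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write a score table as CSV: stable column order, empty cells for
    missing values, values at 8 significant digits (so the round-trip is
    exact well beyond 6-figure display precision)."""
    df = table.data.copy()
    for col in df.columns[1:]:
        df[col] = df[col].map(
            lambda v: "" if pd.isna(v) else format(float(v), ".8g")
            if isinstance(v, (int, float, np.floating)) else v
        )
    df.to_csv(path, index=False)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as canonical-column CSV (booleans as 1/0, missing as
    empty cells, numerics at 6 significant digits)."""
    df = cohort.to_dataframe()
    for name in NUMERIC_FIELDS:
        df[name] = df[name].map(
            lambda v: "" if v is None or pd.isna(v) else format(float(v), ".6g"))
    for name in BOOL_FIELDS:
        df[name] = df[name].map(
            lambda v: "" if v is None or (not isinstance(v, (bool, np.bool_))
                                          and pd.isna(v)) else int(bool(v)))
    df.to_csv(path, index=False)


def read_score_table(path: str | Path) -> ScoreTable:
    df = pd.read_csv(path, dtype={"subject_id": str})
    return ScoreTable(df)
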