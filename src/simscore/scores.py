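"""Continuous metabolic-syndrome scores and derived clinical measures.

The central quantity is the siMS score, a dimensionless composite in which
each metabolic-syndrome component is divided by its diagnostic cutoff and
the terms are summed (HDL entering negatively, waist scaled by height):

    siMS = 2*waist/height + glucose/5.6 + Tg/1.7 + SBP/130 - HDL/1.02 (m)
                                                           - HDL/1.28 (f)

The siMS risk score extends it with the two major non-modifiable risk
factors — age, relative to a sex-specific reference age (45 male / 50
female), and family history of cardio/cerebro-vascular events (factor 1.2
when positive):

    siMS_risk = siMS * age/age_ref(sex) * (1.2 if family history else 1)

All cutoffs come from :class:`~simscore.config.ReferenceConfig`, so
population- or laboratory-specific reference values can be substituted.
Scores are kept at full floating-point precision internally; two-decimal
rounding is a display concern only (:func:`display_round`).

Missing inputs yield a missing result (``None``), never a silent default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort, ScoreTable, Subject
from .config import DEFAULT_CONFIG, ReferenceConfig

logger = logging.getLogger(__name__)


class MissingDataError(ValueError):
    """Raised in strict mode when a required input is missing."""


@dataclass(frozen=True)
class ScoreResult:
    """A computed score with its provenance."""

    value: float
    inputs_used: tuple[str, ...]
    reference_used: ReferenceConfig

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError("score value must be finite")
        if not self.inputs_used:
            raise ValueError("inputs_used must be non-empty")


def display_round(value: Optional[float], ndigits: int = 2) -> Optional[float]:
    """Round-half-up presentation rounding (2 decimals by default).

    Decimal-aware, so 2.005 -> 2.01 despite its binary representation.
    """
    if value is None:
        return None
    import decimal

    d = decimal.Decimal(repr(value)).quantize(
        decimal.Decimal(1).scaleb(-ndigits), rounding=decimal.ROUND_HALF_UP)
    return float(d)


_SIMS_INPUTS = ("waist", "height", "glucose", "triglycerides",
                "systolic_bp", "hdl")


def _require(s: Subject, names: tuple[str, ...], strict: bool,
             what: str) -> bool:
    missing = [n for n in names if getattr(s, n) is None]
    if missing:
        if strict:
            raise MissingDataError(
                f"subject {s.subject_id!r}: cannot compute {what}; "
                f"missing {', '.join(missing)}"
            )
        return False
    return True


def sims_score(s: Subject, r: ReferenceConfig = DEFAULT_CONFIG,
               strict: bool = False) -> Optional[float]:
    """siMS score, or None if a required input is missing.

    With ``r.tg_double_ref`` the triglyceride term is divided by twice the
    reference value, a published variant that slightly increases agreement
    with cohort-fitted scores at the cost of a different scale.
    """
    if not _require(s, _SIMS_INPUTS, strict, "siMS score"):
        return None
    tg_den = 2 * r.tg_ref if r.tg_double_ref else r.tg_ref
    return (
        2 * s.waist / s.height
        + s.glucose / r.gly_ref
        + s.triglycerides / tg_den
        + s.systolic_bp / r.sbp_ref
        - s.hdl / r.hdl_ref(s.sex)
    )


def sims_risk_score(s: Subject, r: ReferenceConfig = DEFAULT_CONFIG,
                    strict: bool = False,
                    assume_no_family_history: bool = False) -> Optional[float]:
    """siMS risk score = siMS * age/age_ref(sex) * family-history factor.

    ``family_history_cv`` is three-valued: an unknown history makes the
    risk score missing unless ``assume_no_family_history`` explicitly
    downgrades unknown to "no event" (factor 1).
    """
    base = sims_score(s, r, strict=strict)
    if base is None:
        return None
    if not _require(s, ("age",), strict, "siMS risk score"):
        return None
    fh = s.family_history_cv
    if fh is None:
        if not assume_no_family_history:
            if strict:
                raise MissingDataError(
                    f"subject {s.subject_id!r}: family_history_cv unknown"
                )
            return None
        fh = False
    factor = r.family_history_multiplier if fh else 1.0
    return base * (s.age / r.age_ref(s.sex)) * factor


def bmi(s: Subject, strict: bool = False) -> Optional[float]:
    """Body-mass index, kg/m² (height is stored in cm)."""
    if not _require(s, ("weight", "height"), strict, "BMI"):
        return None
    h_m = s.height / 100.0
    return s.weight / (h_m * h_m)


def mean_arterial_pressure(s: Subject, strict: bool = False) -> Optional[float]:
    """MAP = DBP + (SBP - DBP)/3, mmHg."""
    if not _require(s, ("systolic_bp", "diastolic_bp"), strict, "MAP"):
        return None
    return s.diastolic_bp + (s.systolic_bp - s.diastolic_bp) / 3.0


def average_arterial_pressure(s: Subject, strict: bool = False) -> Optional[float]:
    """AvAP = (SBP + DBP)/2, mmHg."""
    if not _require(s, ("systolic_bp", "diastolic_bp"), strict, "AvAP"):
        return None
    return (s.systolic_bp + s.diastolic_bp) / 2.0


def homa_ir(s: Subject, strict: bool = False) -> Optional[float]:
    """HOMA-IR = fasting insulin (mIU/L) × fasting glucose (mmol/L) / 22.5."""
    if not _require(s, ("insulin", "glucose"), strict, "HOMA-IR"):
        return None
    return s.insulin * s.glucose / 22.5


def score_cohort(c: Cohort, r: ReferenceConfig = DEFAULT_CONFIG,
                 assume_no_family_history: bool = False,
                 include_components: bool = True) -> ScoreTable:
    """Score every subject, propagating missingness per subject and score.

    Returns a :class:`ScoreTable` with siMS, siMS risk, the derived
    measures and (optionally) the dichotomous component count / status.
    Complete-case counts per column are available via ``table.counts()``.
    """
    from .classifier import classify  # local import: avoids cycle

    if len(c) == 0:
        logger.warning("scoring an empty cohort")
    rows = []
    for s in c:
        row: dict = {"subject_id": s.subject_id}
        row["sims_score"] = sims_score(s, r)
        row["sims_risk_score"] = sims_risk_score(
            s, r, assume_no_family_history=assume_no_family_history)
        row["bmi"] = bmi(s)
        row["map"] = mean_arterial_pressure(s)
        row["avap"] = average_arterial_pressure(s)
        row["homa_ir"] = homa_ir(s)
        if include_components:
            flags = classify(s, r)
            row["ms_components"] = flags.count if flags is not None else None
            row["ms_present"] = (
                None if flags is None or flags.ms_present is None
                else int(flags.ms_present)
            )
        rows.append(row)
    columns = ["subject_id", "sims_score", "sims_risk_score", "bmi", "map",
               "avap", "homa_ir"]
    if include_components:
        columns += ["ms_components", "ms_present"]
    df = pd.DataFrame(rows, columns=columns)
    for col in df.columns[1:]:
        df[col] = pd.to_numeric(df[col])
    table = ScoreTable(df)
    counts = table.counts()
    logger.info("complete-case counts: %s",
                ", ".join(f"{k}={v}" for k, v in counts.items()))
    return table
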