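"""Dichotomous metabolic-syndrome classification.

Adults are classified by the 2009 joint harmonised definition: the
syndrome is present when at least 3 of 5 criteria are met — abdominal
obesity (waist >= 94 cm men / 80 cm women), elevated triglycerides
(>= 1.7 mmol/L), reduced HDL (< 1.03 / < 1.29 mmol/L), raised blood
pressure (systolic >= 130 or diastolic >= 85 mmHg), and elevated fasting
glucose (>= 5.6 mmol/L).  Drug treatment for a component counts as a
fulfilled criterion regardless of the measured value.

Children and adolescents follow the IDF pediatric consensus shape: below
10 years classification is undefined; from 10 to <16 the syndrome requires
abdominal obesity (waist at or above its age/sex 90th percentile) plus at
least two of the remaining four criteria; from 16 the adult rule applies.

Flags are three-valued (True / False / missing): a component with neither
a measurement nor a treatment flag is missing, and syndrome status is
reported missing whenever the missing flags leave the >= 3 decision
genuinely ambiguous — never imputed, because this classification serves as
ROC ground truth downstream and must not bias prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .cohort import Subject
from .config import DEFAULT_CONFIG, ReferenceConfig

logger = logging.getLogger(__name__)

_FLAG_NAMES = ("waist_flag", "tg_flag", "hdl_flag", "bp_flag", "glucose_flag")


@dataclass(frozen=True)
class ComponentFlags:
    """Per-component criterion flags plus the aggregate decision.

    ``count`` is the number of flags known True (missing when any flag is
    missing); ``ms_present`` is the rule's aggregate decision, missing when
    the missing flags make it ambiguous.
    """

    waist_flag: Optional[bool]
    tg_flag: Optional[bool]
    hdl_flag: Optional[bool]
    bp_flag: Optional[bool]
    glucose_flag: Optional[bool]
    count: Optional[int]
    ms_present: Optional[bool]

    def flags(self) -> tuple[Optional[bool], ...]:
        return (self.waist_flag, self.tg_flag, self.hdl_flag,
                self.bp_flag, self.glucose_flag)


def _count_and_presence(flags: tuple[Optional[bool], ...]
                        ) -> tuple[Optional[int], Optional[bool]]:
    n_true = sum(1 for f in flags if f is True)
    n_missing = sum(1 for f in flags if f is None)
    count = n_true if n_missing == 0 else None
    if n_true >= 3:
        present: Optional[bool] = True
    elif n_true + n_missing < 3:
        present = False
    else:
        present = None
    return count, present


def _tg_flag(s: Subject, cutoff: float) -> Optional[bool]:
    if s.treated_lipids:
        return True
    return None if s.triglycerides is None else s.triglycerides >= cutoff


def _hdl_flag(s: Subject, cutoff: float) -> Optional[bool]:
    if s.treated_hdl:
        return True
    return None if s.hdl is None else s.hdl < cutoff


def _bp_flag(s: Subject, sbp_cut: float, dbp_cut: float) -> Optional[bool]:
    if s.treated_bp:
        return True
    sys_hi = None if s.systolic_bp is None else s.systolic_bp >= sbp_cut
    dia_hi = None if s.diastolic_bp is None else s.diastolic_bp >= dbp_cut
    if sys_hi or dia_hi:                      # either known elevated
        return True
    if sys_hi is None and dia_hi is None:
        return None
    if sys_hi is None or dia_hi is None:      # one normal, one unknown
        return None
    return False


def _glucose_flag(s: Subject, cutoff: float) -> Optional[bool]:
    if s.treated_glucose:
        return True
    return None if s.glucose is None else s.glucose >= cutoff


def classify_adult(s: Subject,
                   r: ReferenceConfig = DEFAULT_CONFIG) -> ComponentFlags:
    """Harmonised 2009 adult classification (>= 3 of 5 criteria)."""
    waist = (None if s.waist is None else s.waist >= r.waist_class(s.sex))
    flags = (
        waist,
        _tg_flag(s, r.tg_ref),
        _hdl_flag(s, r.hdl_class(s.sex)),
        _bp_flag(s, r.sbp_ref, r.dbp_ref),
        _glucose_flag(s, r.gly_ref),
    )
    count, present = _count_and_presence(flags)
    return ComponentFlags(*flags, count=count, ms_present=present)


def classify_pediatric(s: Subject,
                       r: ReferenceConfig = DEFAULT_CONFIG
                       ) -> Optional[ComponentFlags]:
    """IDF-style pediatric classification; None below the defined age."""
    ped = r.pediatric
    if s.age is None:
        return None
    if s.age < ped.min_age:
        logger.warning("subject %r: age %.1f below pediatric definition "
                       "minimum (%.0f); classification undefined",
                       s.subject_id, s.age, ped.min_age)
        return None
    if s.age >= ped.adult_rule_age:
        return classify_adult(s, r)

    cutoff = ped.waist_cutoff(s.sex, s.age)
    if cutoff is None:
        logger.warning("subject %r: no waist percentile reference for "
                       "sex=%s age=%d", s.subject_id, s.sex, int(s.age))
        waist = None
    else:
        waist = None if s.waist is None else s.waist >= cutoff
    others = (
        _tg_flag(s, ped.tg_ref),
        _hdl_flag(s, ped.hdl_ref),
        _bp_flag(s, ped.sbp_ref, ped.dbp_ref),
        _glucose_flag(s, ped.gly_ref),
    )
    flags = (waist,) + others
    n_true = sum(1 for f in flags if f is True)
    n_missing = sum(1 for f in flags if f is None)
    count = n_true if n_missing == 0 else None
    # pediatric rule: waist obligatory, plus >= 2 of the remaining four
    n_other_true = sum(1 for f in others if f is True)
    n_other_missing = sum(1 for f in others if f is None)
    if waist is False:
        present: Optional[bool] = False
    elif waist is None:
        # even an obese waist could not rescue <2 other criteria
        present = False if n_other_true + n_other_missing < 2 else None
    else:
        if n_other_true >= 2:
            present = True
        elif n_other_true + n_other_missing < 2:
            present = False
        else:
            present = None
    return ComponentFlags(*flags, count=count, ms_present=present)


def classify(s: Subject,
             r: ReferenceConfig = DEFAULT_CONFIG) -> Optional[ComponentFlags]:
    """Age-appropriate classification: pediatric below 18, adult from 18."""
    if s.age is None:
        return None
    if s.age < 18:
        return classify_pediatric(s, r)
    return classify_adult(s, r)


def component_count(s: Subject,
                    r: ReferenceConfig = DEFAULT_CONFIG) -> Optional[int]:
    """Number of fulfilled criteria under the age-appropriate rule,
    missing if any flag is missing."""
    flags = classify(s, r)
    return None if flags is None else flags.count
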