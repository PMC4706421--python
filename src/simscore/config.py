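"""Reference cutoffs and classifier configuration.

All score formulas and the metabolic-syndrome classifier are parameterised
by :class:`ReferenceConfig`, so national or laboratory-specific cutoffs can
be substituted for the defaults without touching any code.  Defaults follow
the 2009 joint harmonised definition of the metabolic syndrome (IDF / NHLBI
/ AHA / WHF / IAS / IASO joint statement): fasting glucose 5.6 mmol/L,
triglycerides 1.7 mmol/L, systolic pressure 130 mmHg, diastolic 85 mmHg,
waist 94 cm (men) / 80 cm (women), HDL 1.03 / 1.29 mmol/L.

Note one deliberate discrepancy carried by the defaults: the continuous
score divides HDL by 1.02 (men) / 1.28 (women) while the dichotomous
classifier uses the strict 1.03 / 1.29 thresholds.  Both sets are exposed
as separate fields so either convention can be overridden.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping


#: Default pediatric waist-circumference 90th percentiles (cm) by sex and
#: completed year of age, used by the 10-to-<16-year classifier band.
#: These are population-typical placeholder values shipped as editable
#: defaults (synthetic, not taken from any single reference population);
#: studies should substitute percentiles for their own population.
DEFAULT_PEDIATRIC_WAIST_P90: dict[str, dict[int, float]] = {
    "male": {10: 78.0, 11: 81.0, 12: 84.0, 13: 87.0, 14: 89.0, 15: 91.0},
    "female": {10: 75.0, 11: 77.5, 12: 80.0, 13: 82.0, 14: 83.5, 15: 85.0},
}


@dataclass(frozen=True)
class PediatricConfig:
    """Age-banded cutoffs for the pediatric (IDF-style) classifier.

    The rule dispatches on age: below ``min_age`` the classification is
    undefined; in [``min_age``, ``adult_rule_age``) the syndrome requires
    abdominal obesity (waist >= its 90th percentile) plus at least two of
    the four remaining criteria; from ``adult_rule_age`` the adult rule
    applies unchanged.
    """

    min_age: float = 10.0
    adult_rule_age: float = 16.0
    waist_p90: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: {
            sex: dict(tab) for sex, tab in DEFAULT_PEDIATRIC_WAIST_P90.items()
        }
    )
    tg_ref: float = 1.7
    hdl_ref: float = 1.03       # sex-independent below 16 per IDF consensus
    sbp_ref: float = 130.0
    dbp_ref: float = 85.0
    gly_ref: float = 5.6

    def waist_cutoff(self, sex: str, age: float) -> float | None:
        """90th-percentile waist cutoff for a child, or None if not tabulated."""
        table = self.waist_p90.get(sex)
        if table is None:
            return None
        # JSON round-trips integer keys as strings
        return table.get(int(age)) or table.get(str(int(age)))  # type: ignore[arg-type]


@dataclass(frozen=True)
class ReferenceConfig:
    """Cutoffs and multipliers parameterising the continuous scores and the
    dichotomous classifier.

    Score-formula denominators (``*_ref``) and classifier thresholds
    (``*_class``/``waist_*``) are distinct fields: the published score uses
    HDL denominators 1.02/1.28 while the harmonised classifier thresholds
    are 1.03/1.29.
    """

    # continuous-score denominators
    gly_ref: float = 5.6
    tg_ref: float = 1.7
    sbp_ref: float = 130.0
    hdl_ref_male: float = 1.02
    hdl_ref_female: float = 1.28
    # risk-score parameters
    age_ref_male: float = 45.0
    age_ref_female: float = 50.0
    family_history_multiplier: float = 1.2
    # variant: divide triglycerides by twice the reference value
    tg_double_ref: bool = False
    # dichotomous classifier cutoffs (adult)
    waist_male: float = 94.0
    waist_female: float = 80.0
    hdl_class_male: float = 1.03
    hdl_class_female: float = 1.29
    dbp_ref: float = 85.0
    pediatric: PediatricConfig = field(default_factory=PediatricConfig)

    def __post_init__(self) -> None:
        for name in (
            "gly_ref", "tg_ref", "sbp_ref", "hdl_ref_male", "hdl_ref_female",
            "age_ref_male", "age_ref_female", "waist_male", "waist_female",
            "hdl_class_male", "hdl_class_female", "dbp_ref",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"reference cutoff {name!r} must be positive")
        if self.family_history_multiplier < 1:
            raise ValueError("family_history_multiplier must be >= 1")

    def hdl_ref(self, sex: str) -> float:
        return self.hdl_ref_male if sex == "male" else self.hdl_ref_female

    def age_ref(self, sex: str) -> float:
        return self.age_ref_male if sex == "male" else self.age_ref_female

    def waist_class(self, sex: str) -> float:
        return self.waist_male if sex == "male" else self.waist_female

    def hdl_class(self, sex: str) -> float:
        return self.hdl_class_male if sex == "male" else self.hdl_class_female

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceConfig":
        d = dict(d)
        ped = d.pop("pediatric", None)
        if ped is not None and not isinstance(ped, PediatricConfig):
            ped = PediatricConfig(**ped)
        return cls(**d, **({"pediatric": ped} if ped is not None else {}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


DEFAULT_CONFIG = ReferenceConfig()
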