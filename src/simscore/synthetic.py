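"""Seeded synthetic cohorts with metabolic-syndrome structure.

The generator emulates the kind of mixed-age, obesity-enriched clinical
sample on which continuous metabolic-syndrome scores are validated: two
sexes (~34.5% male), a three-group age mixture spanning roughly 7–77
years (children / young adults / adults), and metabolic components that
co-vary because a single latent severity factor loads on all of them —
the single-factor structure repeatedly reported for the syndrome, and the
reason cutoff-normalised, z-sum and PCA scores agree with each other.

Each component is drawn as

    value = mean + age_effect * (age - 40) + sex_effect * male
                 + loading * severity + noise,

on its modelling scale (log scale for triglycerides and insulin, so both
are strictly positive after exponentiation).  Diastolic pressure is
generated as systolic minus a positive pulse-pressure draw, guaranteeing
SBP > DBP.  Waist is derived from the waist-to-height ratio so that body
size and severity interact plausibly; weight comes from a BMI draw.
Missingness is applied last, independently per field.

Defaults for the sex ratio and the age mixture follow published cohort
descriptives for a 528-subject clinical sample; the remaining parameters
are this package's own calibration, chosen so that metabolic-syndrome
prevalence lands near 47% (see ``scripts/calibrate_generator.py``).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .cohort import Cohort, Subject

_COMPONENT_KEYS = ("wht", "glucose", "log_tg", "hdl", "sbp",
                   "log_insulin", "bmi")


def _default_means() -> dict:
    return {"wht": 0.60, "glucose": 5.3, "log_tg": math.log(1.6),
            "hdl": 1.25, "sbp": 124.0, "log_insulin": math.log(11.0),
            "bmi": 31.5}


def _default_loadings() -> dict:
    return {"wht": 0.045, "glucose": 0.45, "log_tg": 0.28, "hdl": -0.13,
            "sbp": 7.0, "log_insulin": 0.45, "bmi": 4.2}


def _default_noise() -> dict:
    return {"wht": 0.040, "glucose": 0.45, "log_tg": 0.30, "hdl": 0.15,
            "sbp": 9.0, "log_insulin": 0.40, "bmi": 3.0}


def _default_age_effects() -> dict:
    return {"wht": 0.0005, "glucose": 0.012, "log_tg": 0.003, "sbp": 0.35}


def _default_sex_effects() -> dict:
    return {"wht": 0.010, "hdl": -0.15, "sbp": 3.0}


def _default_missingness() -> dict:
    return {"waist": 0.012, "height": 0.005, "weight": 0.02,
            "systolic_bp": 0.012, "diastolic_bp": 0.03,
            "glucose": 0.012, "insulin": 0.12, "triglycerides": 0.012,
            "hdl": 0.012, "family_history_cv": 0.02}


@dataclass
class SyntheticCohortConfig:
    """Distributional parameters of the synthetic cohort generator."""

    n: int = 528
    seed: int = 0
    sex_ratio_male: float = 0.345
    age_weights: tuple[float, float, float] = (0.138, 0.305, 0.557)
    age_means: tuple[float, float, float] = (13.2, 24.3, 48.2)
    age_sds: tuple[float, float, float] = (2.8, 3.4, 10.6)
    age_range: tuple[float, float] = (7.0, 77.0)
    family_history_prevalence: float = 0.30
    severity_sd: float = 1.0
    means: Mapping[str, float] = field(default_factory=_default_means)
    loadings: Mapping[str, float] = field(default_factory=_default_loadings)
    noise_sds: Mapping[str, float] = field(default_factory=_default_noise)
    age_effects: Mapping[str, float] = field(default_factory=_default_age_effects)
    sex_effects: Mapping[str, float] = field(default_factory=_default_sex_effects)
    height_means: Mapping[str, float] = field(
        default_factory=lambda: {"male": 177.0, "female": 164.0})
    height_sd: float = 7.0
    bp_gap_mean: float = 45.0
    bp_gap_sd: float = 7.0
    bp_gap_min: float = 8.0
    missingness_rates: Mapping[str, float] = field(
        default_factory=_default_missingness)

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not 0 <= self.sex_ratio_male <= 1:
            raise ValueError("sex_ratio_male must lie in [0, 1]")
        if abs(sum(self.age_weights) - 1.0) > 1e-9:
            raise ValueError("age_weights must sum to 1")
        if any(sd <= 0 for sd in self.age_sds) or self.height_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if self.severity_sd <= 0:
            raise ValueError("severity_sd must be positive")
        for key in _COMPONENT_KEYS:
            for mapping, name in ((self.means, "means"),
                                  (self.loadings, "loadings"),
                                  (self.noise_sds, "noise_sds")):
                if key not in mapping:
                    raise ValueError(f"{name} missing component {key!r}")
            if self.noise_sds[key] <= 0:
                raise ValueError(f"noise sd for {key!r} must be positive")
        for k, v in self.missingness_rates.items():
            if not 0 <= v <= 1:
                raise ValueError(f"missingness rate for {k!r} outside [0,1]")
        if not 0 <= self.family_history_prevalence <= 1:
            raise ValueError("family_history_prevalence outside [0,1]")
        if self.bp_gap_min <= 0:
            raise ValueError("bp_gap_min must be positive")


def _growth_factor(age: np.ndarray) -> np.ndarray:
    """Fraction of adult height attained; linear from 0.70 at 7 y to 1 at 18."""
    return np.clip(0.70 + 0.30 * (age - 7.0) / 11.0, 0.70, 1.0)


def generate_cohort(cfg: SyntheticCohortConfig) -> Cohort:
    """Draw a synthetic cohort; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    provenance = f"synthetic(seed={cfg.seed}, n={n})"
    if n == 0:
        return Cohort([], provenance=provenance)

    male = rng.random(n) < cfg.sex_ratio_male
    group = rng.choice(3, size=n, p=list(cfg.age_weights))
    age = rng.normal(np.take(cfg.age_means, group),
                     np.take(cfg.age_sds, group))
    age = np.clip(age, *cfg.age_range)

    severity = rng.normal(0.0, cfg.severity_sd, size=n)

    adult_height = np.where(
        male,
        rng.normal(cfg.height_means["male"], cfg.height_sd, size=n),
        rng.normal(cfg.height_means["female"], cfg.height_sd, size=n))
    height = adult_height * _growth_factor(age)

    def draw(key: str) -> np.ndarray:
        m = cfg.means[key] + cfg.loadings[key] * severity
        m = m + cfg.age_effects.get(key, 0.0) * (age - 40.0)
        m = m + cfg.sex_effects.get(key, 0.0) * male
        return m + rng.normal(0.0, cfg.noise_sds[key], size=n)

    wht = np.clip(draw("wht"), 0.35, None)
    waist = wht * height
    glucose = np.clip(draw("glucose"), 3.0, None)
    tg = np.exp(draw("log_tg"))
    hdl = np.clip(draw("hdl"), 0.40, None)
    sbp = np.clip(draw("sbp"), 90.0, None)
    gap = np.maximum(rng.normal(cfg.bp_gap_mean, cfg.bp_gap_sd, size=n),
                     cfg.bp_gap_min)
    dbp = sbp - gap
    insulin = np.exp(draw("log_insulin"))
    bmi_vals = np.clip(draw("bmi"), 15.0, None)
    weight = bmi_vals * (height / 100.0) ** 2
    family = rng.random(n) < cfg.family_history_prevalence

    values: dict[str, np.ndarray] = {
        "waist": waist, "height": height, "weight": weight,
        "systolic_bp": sbp, "diastolic_bp": dbp, "glucose": glucose,
        "insulin": insulin, "triglycerides": tg, "hdl": hdl,
    }
    miss: dict[str, np.ndarray] = {}
    for fname in list(values) + ["family_history_cv"]:
        rate = cfg.missingness_rates.get(fname, 0.0)
        miss[fname] = rng.random(n) < rate

    width = max(4, len(str(n)))
    subjects = []
    for i in range(n):
        def get(fname: str) -> Optional[float]:
            return None if miss[fname][i] else float(values[fname][i])

        sbp_i, dbp_i = get("systolic_bp"), get("diastolic_bp")
        if sbp_i is not None and dbp_i is not None and sbp_i <= dbp_i:
            dbp_i = None  # cannot occur by construction, kept as guard
        subjects.append(Subject(
            subject_id=f"S{i + 1:0{width}d}",
            sex="male" if male[i] else "female",
            age=float(age[i]),
            height=get("height"),
            weight=get("weight"),
            waist=get("waist"),
            systolic_bp=sbp_i,
            diastolic_bp=dbp_i,
            glucose=get("glucose"),
            insulin=get("insulin"),
            triglycerides=get("triglycerides"),
            hdl=get("hdl"),
            family_history_cv=(None if miss["family_history_cv"][i]
                               else bool(family[i])),
        ))
    return Cohort(subjects, provenance=provenance)


# ---------------------------------------------------------------------------
# worked-example fixture


def table2_fixture() -> Cohort:
    """Ten worked-example subjects: five patients, each at baseline and at
    a follow-up visit, with complete score inputs.

    These are the published worked examples for the siMS and siMS risk
    scores (sex, family history and all six score inputs per row), useful
    for exact end-to-end checks of the scoring pipeline.
    """
    #        id            sex  waist height sbp  hdl   tg    gly  age  fh
    rows = [
        ("p1_baseline",  "female", 132, 167, 120, 0.91, 2.49, 5.7, 20, True),
        ("p1_followup",  "female", 120, 168, 120, 1.45, 1.31, 5.2, 22, True),
        ("p2_baseline",  "male",   104, 190, 140, 1.03, 2.09, 5.5, 30, True),
        ("p2_followup",  "male",   103, 190, 140, 1.10, 1.90, 5.4, 37, True),
        ("p3_baseline",  "female",  99, 161, 130, 1.17, 2.88, 5.0, 53, False),
        ("p3_followup",  "female",  93, 161, 120, 1.30, 1.90, 5.3, 54, False),
        ("p4_baseline",  "female",  95, 161, 160, 1.19, 1.80, 5.2, 42, True),
        ("p4_followup",  "female",  90, 161, 130, 1.20, 1.60, 5.0, 52, True),
        ("p5_baseline",  "male",   141, 180, 125, 1.25, 1.58, 5.3, 36, False),
        ("p5_followup",  "male",   131, 180, 110, 1.20, 1.40, 5.4, 39, False),
    ]
    subjects = [
        Subject(subject_id=sid, sex=sex, waist=float(w), height=float(h),
                systolic_bp=float(sbp), hdl=hdl, triglycerides=tg,
                glucose=gly, age=float(a), family_history_cv=fh)
        for sid, sex, w, h, sbp, hdl, tg, gly, a, fh in rows
    ]
    return Cohort(subjects, provenance="worked-example fixture")
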