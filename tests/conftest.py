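import numpy as np
import pytest

from simscore import (Cohort, ReferenceConfig, Subject, SyntheticCohortConfig,
                      generate_cohort, table2_fixture)

#: printed worked-example scores, keyed by subject id:
#: (siMS, siMS risk, rounds_cleanly) — three cells disagree with the exact
#: formula by one unit in the last decimal (apparent truncation in print)
TABLE2_PRINTED = {
    "p1_baseline": (4.28, 2.05, True),
    "p1_followup": (2.92, 1.54, True),
    "p2_baseline": (3.37, 2.69, False),   # risk prints 2.69, formula 2.6987
    "p2_followup": (3.17, 3.12, False),   # siMS prints 3.17, formula 3.1646
    "p3_baseline": (3.90, 4.14, True),
    "p3_followup": (3.13, 3.38, True),
    "p4_baseline": (3.46, 3.49, False),   # formula 3.4686 / 3.4963
    "p4_followup": (3.01, 3.76, True),
    "p5_baseline": (3.18, 2.54, True),
    "p5_followup": (2.91, 2.52, True),
}


@pytest.fixture(scope="session")
def table2():
    return table2_fixture()


@pytest.fixture
def ref():
    return ReferenceConfig()


@pytest.fixture(scope="session")
def synthetic_cohort_500():
    """The default synthetic validation cohort (seed 1, n = 500)."""
    return generate_cohort(SyntheticCohortConfig(n=500, seed=1))


def make_subject(**kw):
    """A complete, metabolically unremarkable adult female."""
    base = dict(subject_id="s", sex="female", age=40.0, height=165.0,
                weight=70.0, waist=80.0, systolic_bp=120.0,
                diastolic_bp=78.0, glucose=5.0, insulin=10.0,
                triglycerides=1.2, hdl=1.5, family_history_cv=False)
    base.update(kw)
    return Subject(**base)


def random_complete_cohort(rng: np.random.Generator, n: int) -> Cohort:
    """Small random complete-case cohort for oracle comparisons."""
    subjects = []
    for i in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        sbp = rng.uniform(100, 160)
        subjects.append(Subject(
            subject_id=f"r{i}", sex=sex,
            age=float(rng.uniform(18, 70)),
            height=float(rng.uniform(150, 195)),
            weight=float(rng.uniform(50, 120)),
            waist=float(rng.uniform(65, 130)),
            systolic_bp=float(sbp),
            diastolic_bp=float(sbp - rng.uniform(20, 50)),
            glucose=float(rng.uniform(4, 9)),
            insulin=float(rng.uniform(3, 40)),
            triglycerides=float(rng.uniform(0.5, 4.5)),
            hdl=float(rng.uniform(0.7, 2.2)),
            family_history_cv=bool(rng.random() < 0.3),
        ))
    return Cohort(subjects)
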