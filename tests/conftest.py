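import datetime as dt

import pytest

from effshunt import COARSE_GRID, ABGRecord, PhysiologicalAssumptions, build_database
from effshunt.synthetic import CohortSpec, generate_cohort

T0 = dt.datetime(2024, 1, 1, 8, 0)


def rec(minutes, fio2, pao2, paco2, ph=7.40, hb=110.0, ventilated=True, pid="A"):
    return ABGRecord(
        patient_id=pid,
        timestamp=T0 + dt.timedelta(minutes=minutes),
        fio2=fio2,
        pao2=pao2,
        paco2=paco2,
        ph=ph,
        hb=hb,
        ventilated=ventilated,
    )


@pytest.fixture(scope="session")
def assumptions():
    return PhysiologicalAssumptions()


@pytest.fixture(scope="session")
def toy_records():
    """Hand-enumerated pair-selection fixture for one patient.

    Qualifying weaning pairs are exactly (r1,r2), (r1,r3), (r2,r6), (r4,r6):
    (r1,r4) spans 181 min, (r2,r3) raises FiO2, (r2,r4) and (r3,r6) change
    PaCO2 by exactly 0.3 kPa (strict <), r5 is not ventilated, and (r2,r6)
    spans exactly 180 min (inclusive window).
    """
    return [
        rec(0, 0.60, 12.0, 5.0),  # r1
        rec(60, 0.50, 11.0, 5.1),  # r2
        rec(120, 0.55, 11.5, 5.0),  # r3
        rec(181, 0.40, 10.0, 5.4),  # r4
        rec(200, 0.35, 9.5, 5.4, ventilated=False),  # r5
        rec(240, 0.30, 9.0, 5.3),  # r6
    ]


@pytest.fixture(scope="session")
def toy_expected_pairs():
    """(first_minute, second_minute) of the qualifying pairs, in order."""
    return [(0, 60), (0, 120), (60, 240), (181, 240)]


@pytest.fixture(scope="session")
def small_cohort(assumptions):
    records, truth = generate_cohort(CohortSpec(n_patients=40, seed=42), assumptions)
    return records, truth


@pytest.fixture(scope="session")
def coarse_db(assumptions):
    return build_database(COARSE_GRID, assumptions)
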