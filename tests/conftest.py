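import pytest

from szrec.codes import default_registry
from szrec.records import DiagnosisCode, Encounter, PatientRecord
from szrec.simulate import SimConfig, claims_default_config, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def enc(date, codes, setting="outpatient", primary=0, admitting=None):
    """Terse encounter builder: codes as (code, dialect) pairs."""
    return Encounter(date=date, setting=setting,
                     codes=[DiagnosisCode(c, d) for c, d in codes],
                     primary_code=primary, admitting_code=admitting)


FILLER = ("Z00.129", "icd10")


@pytest.fixture(scope="session")
def hand_cohort():
    """Six hand-built patients: two pass all criteria, and each of the three
    inclusion criteria (plus the age gate) is violated exactly once."""
    idx = 1200
    return [
        # P1: child, prior contact 400d before, follow-up 750d after -> in
        PatientRecord("P1", birth_date=idx - 2000, sex="F", encounters=[
            enc(idx - 400, [FILLER]),
            enc(idx, [("R56.9", "icd10")]),
            enc(idx + 750, [FILLER]),
        ]),
        # P2: infant (180d), well-child visit 10d before, follow-up -> in
        PatientRecord("P2", birth_date=idx - 180, sex="M", encounters=[
            enc(idx - 10, [FILLER]),
            enc(idx, [("G40.909", "icd10")]),
            enc(idx + 800, [FILLER]),
        ]),
        # P3: prior contact only 200d before index at age ~5y -> out
        PatientRecord("P3", birth_date=idx - 1800, sex="F", encounters=[
            enc(idx - 200, [FILLER]),
            enc(idx, [("780.39", "icd9")]),
            enc(idx + 750, [FILLER]),
        ]),
        # P4: no seizure-like code anywhere -> out (no index event)
        PatientRecord("P4", birth_date=idx - 1800, sex="M", encounters=[
            enc(idx - 400, [FILLER]),
            enc(idx, [FILLER]),
            enc(idx + 750, [FILLER]),
        ]),
        # P5: follow-up only 600d after index -> out
        PatientRecord("P5", birth_date=idx - 1800, sex="F", encounters=[
            enc(idx - 400, [FILLER]),
            enc(idx, [("345.90", "icd9")]),
            enc(idx + 600, [FILLER]),
        ]),
        # P6: first seizure-like code at age 22y -> out (age gate)
        PatientRecord("P6", birth_date=idx - 22 * 365, sex="M", encounters=[
            enc(idx - 400, [FILLER]),
            enc(idx, [("G40.909", "icd10")]),
            enc(idx + 750, [FILLER]),
        ]),
    ]


@pytest.fixture(scope="session")
def small_emr_cohort():
    return generate_cohort(SimConfig(n_patients=250, seed=42))


@pytest.fixture(scope="session")
def small_claims_cohort():
    return generate_cohort(claims_default_config(n_patients=250, seed=43))
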