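import copy

import pytest

from szrec.cohort import find_index_event
from szrec.outcomes import (
    CRITERION_FIELDS,
    OutcomeConfig,
    composite_label,
    criterion_asm,
    criterion_procedure,
    criterion_status_epilepticus,
    criterion_utilisation,
    is_epilepsy_specific,
    label_cohort,
)
from szrec.records import DiagnosisCode, MedicationRecord, PatientRecord, ProcedureRecord
from szrec.simulate import claims_default_config, generate_cohort
from szrec.cohort import build_cohort

from conftest import enc, FILLER
from _oracles import oracle_outcome

IDX = 1200
CFG = OutcomeConfig()


def base_patient(extra_encs=(), meds=(), procs=()):
    p = PatientRecord("X", birth_date=IDX - 2000, sex="F", encounters=[
        enc(IDX - 400, [FILLER]),
        enc(IDX, [("R56.9", "icd10")]),
        *extra_encs,
        enc(IDX + 750, [FILLER]),
    ], medications=list(meds), procedures=list(procs))
    p.encounters.sort(key=lambda e: e.date)
    return p


def index_of(p, registry):
    return find_index_event(p, registry)


@pytest.mark.parametrize("code,dialect,expected", [
    ("G40.311", "icd10", True),
    ("345.10", "icd9", True),
    ("R56.9", "icd10", False),   # convulsions excluded
    ("780.39", "icd9", False),
    ("G41.9", "icd10", False),
])
def test_epilepsy_specific_prefixes(code, dialect, expected, registry):
    assert is_epilepsy_specific(DiagnosisCode(code, dialect),
                                registry) is expected


def test_epilepsy_specific_rejects_unknown_dialect(registry):
    with pytest.raises(ValueError, match="dialect"):
        is_epilepsy_specific(DiagnosisCode("G40.9", "snomed"), registry)


def test_status_epilepticus_positional_rules(registry):
    se = ("G40.901", "icd10")
    # primary position -> fires
    p = base_patient([enc(IDX + 30, [se, FILLER], primary=0)])
    assert criterion_status_epilepticus(p, index_of(p, registry), registry, CFG)
    # third position, filler primary, no admitting -> does not fire
    p2 = base_patient([enc(IDX + 30, [FILLER, ("J06.9", "icd10"), se],
                           primary=0)])
    assert not criterion_status_epilepticus(p2, index_of(p2, registry),
                                            registry, CFG)
    # third position but admitting code is epilepsy-specific -> fires
    p3 = base_patient([enc(IDX + 30, [FILLER, se, ("G40.9", "icd10")],
                           primary=0, admitting=2)])
    assert criterion_status_epilepticus(p3, index_of(p3, registry),
                                        registry, CFG)


def test_procedure_requires_week_later_confirmation(registry):
    proc = ProcedureRecord(date=IDX + 100, code="61533", dialect="cpt")
    anchor = enc(IDX + 100, [("G40.909", "icd10")], setting="inpatient")
    confirm = enc(IDX + 110, [("G40.909", "icd10")])
    p = base_patient([anchor, confirm], procs=[proc])
    assert criterion_procedure(p, index_of(p, registry), registry, CFG)
    # confirmation only 3 days later -> too close
    p2 = base_patient([anchor, enc(IDX + 103, [("G40.909", "icd10")])],
                      procs=[proc])
    assert not criterion_procedure(p2, index_of(p2, registry), registry, CFG)
    # anchoring encounter primary dx is a convulsion, not epilepsy-specific
    p3 = base_patient([enc(IDX + 100, [("R56.9", "icd10")]), confirm],
                      procs=[proc])
    assert not criterion_procedure(p3, index_of(p3, registry), registry, CFG)


def test_asm_needs_same_day_epilepsy_encounter(registry):
    lev = MedicationRecord(date=IDX + 60, drug="levetiracetam")
    p = base_patient([enc(IDX + 60, [("G40.9", "icd10")])], meds=[lev])
    assert criterion_asm(p, index_of(p, registry), registry, CFG)
    # gabapentin on a neuropathic-pain day does not fire
    gaba = MedicationRecord(date=IDX + 60, drug="gabapentin")
    p2 = base_patient([enc(IDX + 60, [("G89.29", "icd10")])], meds=[gaba])
    assert not criterion_asm(p2, index_of(p2, registry), registry, CFG)
    # inside the 7-day blanking window -> never counts
    early = MedicationRecord(date=IDX + 3, drug="levetiracetam")
    p3 = base_patient([enc(IDX + 3, [("G40.9", "icd10")])], meds=[early])
    assert not criterion_asm(p3, index_of(p3, registry), registry, CFG)


def test_unknown_medication_ignored_with_warning(registry, caplog):
    med = MedicationRecord(date=IDX + 60, drug="unobtainium")
    p = base_patient([enc(IDX + 60, [("G40.9", "icd10")])], meds=[med])
    with caplog.at_level("WARNING"):
        assert not criterion_asm(p, index_of(p, registry), registry, CFG)
    assert "unobtainium" in caplog.text


def test_utilisation_distinct_day_semantics(registry):
    sz = ("G40.909", "icd10")
    # two encounters on the same date count as one distinct day
    p = base_patient([enc(IDX + 50, [sz]), enc(IDX + 50, [sz])])
    assert not criterion_utilisation(p, index_of(p, registry), registry,
                                     CFG, "seizure_related")
    p2 = base_patient([enc(IDX + 50, [sz]), enc(IDX + 80, [sz]),
                       enc(IDX + 90, [sz])])
    assert criterion_utilisation(p2, index_of(p2, registry), registry,
                                 CFG, "seizure_related")


def test_blanking_window_excludes_events(registry):
    """Events on or before index + 7 days never contribute to any criterion."""
    sz = ("G40.909", "icd10")
    p = base_patient([enc(IDX + d, [sz], setting="inpatient")
                      for d in (1, 3, 7)],
                     meds=[MedicationRecord(date=IDX + 7,
                                            drug="levetiracetam")])
    label = composite_label(p, index_of(p, registry), registry, CFG)
    assert not label.composite
    # the same events one week later flip several criteria
    p2 = base_patient([enc(IDX + d, [sz], setting="inpatient")
                       for d in (8, 10, 14)])
    assert composite_label(p2, index_of(p2, registry), registry,
                           CFG).composite


def test_composite_is_or_of_criteria(registry):
    p = base_patient()  # no post-index events at all
    label = composite_label(p, index_of(p, registry), registry, CFG)
    assert not any(getattr(label, f) for f in CRITERION_FIELDS)
    assert not label.composite
    # meeting exactly one criterion makes the composite positive
    p2 = base_patient([enc(IDX + 30, [("G40.901", "icd10")], primary=0)])
    label2 = composite_label(p2, index_of(p2, registry), registry, CFG)
    assert label2.status_epilepticus and label2.composite


def test_event_addition_monotone(registry):
    """Adding post-index events never flips any criterion true -> false."""
    sz = ("G40.909", "icd10")
    p = base_patient([enc(IDX + 50, [sz], setting="inpatient"),
                      enc(IDX + 90, [sz])])
    before = composite_label(p, index_of(p, registry), registry, CFG)
    p2 = copy.deepcopy(p)
    p2.encounters.append(enc(IDX + 200, [sz], setting="inpatient"))
    p2.medications.append(MedicationRecord(date=IDX + 90,
                                           drug="levetiracetam"))
    p2.procedures.append(ProcedureRecord(date=IDX + 90, code="95819"))
    p2.encounters.sort(key=lambda e: e.date)
    after = composite_label(p2, index_of(p2, registry), registry, CFG)
    for f in CRITERION_FIELDS + ("composite",):
        assert getattr(after, f) >= getattr(before, f)


def test_label_oracle_equivalence_500(registry):
    """All eight fields match the independent brute-force oracle on a
    500-patient random cohort."""
    records = generate_cohort(claims_default_config(n_patients=500, seed=77))
    cohort = build_cohort(records, registry, "claims")
    labels = label_cohort(records, cohort, registry, CFG)
    by_id = {r.patient_id: r for r in records}
    for _, row in labels.iterrows():
        patient = by_id[row["patient_id"]]
        ev = find_index_event(patient, registry)
        expected = oracle_outcome(patient, ev.index_date)
        got = {f: bool(row[f]) for f in CRITERION_FIELDS + ("composite",)}
        assert got == expected, row["patient_id"]
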