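"""Index-event identification and temporal cohort inclusion.

A patient enters the cohort when three criteria hold around the *index
event*, the earliest encounter carrying a broad seizure-like diagnosis code
(epilepsy, seizures or convulsions) before age 21:

1. prior contact — an encounter (EMR) or insurance coverage (claims) at
   least 365 days before the index event; infants (< 365 days old at index)
   instead need a non-seizure-like encounter at least 7 days before it,
2. a qualifying index encounter before the 21st birthday, and
3. follow-up — any encounter (EMR) or coverage (claims) at least 730 days
   after the index event.

"Before the age of 21 years" is evaluated as index_date < birth + 21*365
days; all window arithmetic is fixed-day.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codes import CodeSetRegistry
from .errors import ConfigurationError, ContractError
from .records import (
    DAYS_PER_WEEK,
    DAYS_PER_YEAR,
    DAYS_TWO_YEARS,
    PatientRecord,
    day_to_iso,
)

AGE_LIMIT_DAYS = 21 * DAYS_PER_YEAR

REASON_NO_INDEX = "no_index_event"
REASON_PRIOR_CONTACT = "prior_contact"
REASON_FOLLOWUP = "followup"


@dataclass(frozen=True)
class IndexEvent:
    patient_id: str
    index_date: int
    qualifying_code: str
    qualifying_dialect: str
    age_at_index_days: int


@dataclass(frozen=True)
class InclusionResult:
    patient_id: str
    has_index: bool
    criterion_prior_contact: bool
    criterion_index: bool
    criterion_followup: bool
    included: bool
    exclusion_reason: str | None


def find_index_event(patient: PatientRecord,
                     registry: CodeSetRegistry) -> IndexEvent | None:
    """Earliest encounter carrying any broad seizure-like code, provided the
    patient was under 21 at that encounter; ``None`` otherwise.

    The age gate applies to the earliest seizure-like encounter itself: a
    patient whose first seizure-like code appears at or after the 21st
    birthday has no index event.
    """
    dates = [e.date for e in patient.encounters]
    if dates != sorted(dates):
        raise ContractError(
            f"{patient.patient_id}: encounters must be date-sorted")
    for enc in patient.encounters:
        matching = [c for c in enc.codes
                    if registry.code_matches("seizure_like_broad", c)]
        if matching:
            age = enc.date - patient.birth_date
            if age < AGE_LIMIT_DAYS:
                return IndexEvent(
                    patient_id=patient.patient_id, index_date=enc.date,
                    qualifying_code=matching[0].code,
                    qualifying_dialect=matching[0].dialect,
                    age_at_index_days=age)
            return None
    return None


def check_inclusion(patient: PatientRecord, index: IndexEvent,
                    registry: CodeSetRegistry,
                    modality: str) -> InclusionResult:
    """Apply the prior-contact and follow-up criteria to an indexed patient."""
    if modality not in ("emr", "claims"):
        raise ConfigurationError(f"unknown modality {modality!r}")
    if modality == "claims" and not patient.coverage:
        raise ConfigurationError(
            f"{patient.patient_id}: claims modality requires coverage periods")

    infant = index.age_at_index_days < DAYS_PER_YEAR
    lead = DAYS_PER_WEEK if infant else DAYS_PER_YEAR

    if modality == "emr":
        if infant:
            # "for other purposes": the qualifying contact must not itself be
            # a seizure-like encounter
            prior = any(
                e.date <= index.index_date - lead
                and not registry.encounter_matches("seizure_like_broad", e)
                for e in patient.encounters)
        else:
            prior = any(e.date <= index.index_date - lead
                        for e in patient.encounters)
        followup = any(e.date >= index.index_date + DAYS_TWO_YEARS
                       for e in patient.encounters)
    else:
        target = index.index_date - lead
        prior = any(c.start <= target <= c.end for c in patient.coverage)
        followup = any(c.end >= index.index_date + DAYS_TWO_YEARS
                       for c in patient.coverage)

    included = prior and followup
    if included:
        reason = None
    elif not prior:
        reason = REASON_PRIOR_CONTACT
    else:
        reason = REASON_FOLLOWUP
    return InclusionResult(
        patient_id=patient.patient_id, has_index=True,
        criterion_prior_contact=prior, criterion_index=True,
        criterion_followup=followup, included=included,
        exclusion_reason=reason)


def _excluded_no_index(patient_id: str) -> InclusionResult:
    return InclusionResult(
        patient_id=patient_id, has_index=False,
        criterion_prior_contact=False, criterion_index=False,
        criterion_followup=False, included=False,
        exclusion_reason=REASON_NO_INDEX)


def build_cohort(records: list[PatientRecord], registry: CodeSetRegistry,
                 modality: str) -> pd.DataFrame:
    """One row per input patient with the index event and inclusion flags."""
    seen = set()
    rows = []
    for patient in records:
        if patient.patient_id in seen:
            raise ValueError(f"duplicate patient_id {patient.patient_id!r}")
        seen.add(patient.patient_id)
        index = find_index_event(patient, registry)
        if index is None:
            res = _excluded_no_index(patient.patient_id)
            row = {"index_date": "", "qualifying_code": "",
                   "age_at_index_days": -1}
        else:
            res = check_inclusion(patient, index, registry, modality)
            row = {"index_date": day_to_iso(index.index_date),
                   "qualifying_code": index.qualifying_code,
                   "age_at_index_days": index.age_at_index_days}
        rows.append({
            "patient_id": res.patient_id,
            "has_index": res.has_index,
            **row,
            "criterion_prior_contact": res.criterion_prior_contact,
            "criterion_index": res.criterion_index,
            "criterion_followup": res.criterion_followup,
            "included": res.included,
            "exclusion_reason": res.exclusion_reason or "",
        })
    columns = ["patient_id", "has_index", "index_date", "qualifying_code",
               "age_at_index_days", "criterion_prior_contact",
               "criterion_index", "criterion_followup", "included",
               "exclusion_reason"]
    return pd.DataFrame(rows, columns=columns)


def index_events(records: list[PatientRecord],
                 registry: CodeSetRegistry) -> dict[str, IndexEvent]:
    """Index events for all patients that have one, keyed by patient id."""
    out = {}
    for patient in records:
        index = find_index_event(patient, registry)
        if index is not None:
            out[patient.patient_id] = index
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, lineterminator="\n")
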