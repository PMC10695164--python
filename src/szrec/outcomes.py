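"""Composite seizure-recurrence label from seven expert-derived measures.

All criteria look only at events in the post-index outcome window
``(index + blanking_days, index + window_days]`` (defaults: 7-day blanking,
730-day window), so the earliest a patient can be considered recurrent is one
week after the index event.  A patient meeting *any* criterion is labelled
recurrent; only patients matching none are labelled seizure-free.

Epilepsy-specific means ICD-9 345.* or ICD-10 G40.*, explicitly excluding the
convulsion families (ICD-9 780.*, ICD-10 R56.*).  "Seizure-related" for the
utilisation / inpatient / diagnostics measures is the broader union of
epilepsy-specific and convulsion codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .codes import CodeSetRegistry
from .cohort import IndexEvent
from .errors import ConfigurationError
from .records import DiagnosisCode, Encounter, PatientRecord

logger = logging.getLogger(__name__)

CRITERION_FIELDS = (
    "asm", "status_epilepticus", "inpatient_seizure", "seizure_utilisation",
    "all_utilisation", "diagnostics", "procedure",
)


@dataclass
class OutcomeConfig:
    window_days: int = 730
    blanking_days: int = 7
    thresholds: dict = field(default_factory=lambda: {
        "seizure_utilisation_min_distinct_days": 2,
        "all_utilisation_min_distinct_days": 4,
        "inpatient_min_admissions": 1,
        "diagnostics_min_count": 1,
    })
    require_adjunctive_only: bool = False
    # "All health-care utilisation" may be read as descriptive rather than a
    # recurrence criterion; when disabled its field is reported False and it
    # drops out of the composite OR.
    include_all_utilisation: bool = True

    def validate(self) -> None:
        if self.blanking_days < 0 or self.window_days <= self.blanking_days:
            raise ConfigurationError(
                "window_days must exceed blanking_days >= 0")
        for key, value in self.thresholds.items():
            if value < 1:
                raise ConfigurationError(f"thresholds[{key}] must be >= 1")


@dataclass(frozen=True)
class OutcomeLabel:
    patient_id: str
    asm: bool
    status_epilepticus: bool
    inpatient_seizure: bool
    seizure_utilisation: bool
    all_utilisation: bool
    diagnostics: bool
    procedure: bool
    composite: bool


def is_epilepsy_specific(code: DiagnosisCode,
                         registry: CodeSetRegistry) -> bool:
    """True iff the code matches an epilepsy-specific prefix (345.*/G40.*);
    convulsion codes (780.*/R56.*) are false by construction."""
    if code.dialect not in ("icd9", "icd10"):
        raise ValueError(f"unknown diagnosis dialect {code.dialect!r}")
    return registry.code_matches("epilepsy_specific", code)


def _in_window(date: int, index: IndexEvent, config: OutcomeConfig) -> bool:
    return (index.index_date + config.blanking_days < date
            <= index.index_date + config.window_days)


def _window_encounters(patient: PatientRecord, index: IndexEvent,
                       config: OutcomeConfig) -> list[Encounter]:
    return [e for e in patient.encounters if _in_window(e.date, index, config)]


def _billing_positions(enc: Encounter) -> list[int]:
    positions = [enc.primary_code]
    if enc.admitting_code is not None:
        positions.append(enc.admitting_code)
    return positions


def _billing_epilepsy_specific(enc: Encounter,
                               registry: CodeSetRegistry) -> bool:
    return any(is_epilepsy_specific(enc.codes[i], registry)
               for i in _billing_positions(enc))


def criterion_status_epilepticus(patient: PatientRecord, index: IndexEvent,
                                 registry: CodeSetRegistry,
                                 config: OutcomeConfig) -> bool:
    """Status epilepticus coded in the window, with the SE code itself in
    primary/admitting position or the primary/admitting code epilepsy-specific
    (filters miscoded incidental mentions)."""
    for enc in _window_encounters(patient, index, config):
        se_positions = [i for i, c in enumerate(enc.codes)
                        if registry.code_matches("status_epilepticus", c)]
        if not se_positions:
            continue
        billing = _billing_positions(enc)
        if any(i in billing for i in se_positions):
            return True
        if _billing_epilepsy_specific(enc, registry):
            return True
    return False


def criterion_procedure(patient: PatientRecord, index: IndexEvent,
                        registry: CodeSetRegistry,
                        config: OutcomeConfig) -> bool:
    """Epilepsy-related procedure in the window whose same-day encounter has
    an epilepsy-specific primary/admitting diagnosis, confirmed by another
    epilepsy-specific diagnosis at least 7 days after the procedure."""
    for proc in patient.procedures:
        if not _in_window(proc.date, index, config):
            continue
        if not registry.matches("epilepsy_procedures", proc.code,
                                proc.dialect):
            continue
        anchored = any(
            enc.date == proc.date
            and _billing_epilepsy_specific(enc, registry)
            for enc in patient.encounters)
        if not anchored:
            continue
        confirmed = any(
            enc.date >= proc.date + 7
            and any(is_epilepsy_specific(c, registry) for c in enc.codes)
            for enc in patient.encounters)
        if confirmed:
            return True
    return False


def criterion_asm(patient: PatientRecord, index: IndexEvent,
                  registry: CodeSetRegistry, config: OutcomeConfig) -> bool:
    """An ASM record in the window on the same calendar day as an encounter
    carrying an epilepsy-specific diagnosis.  Same-day rather than
    same-encounter co-occurrence: claims data lack encounter linkage."""
    epilepsy_days = {
        enc.date for enc in patient.encounters
        if any(is_epilepsy_specific(c, registry) for c in enc.codes)}
    for med in patient.medications:
        if not _in_window(med.date, index, config):
            continue
        entry = registry.asm_lexicon.get(med.drug.lower())
        if entry is None:
            logger.warning("medication %r not in ASM lexicon; ignored",
                           med.drug)
            continue
        if config.require_adjunctive_only and not entry.adjunctive:
            continue
        if med.date in epilepsy_days:
            return True
    return False


def criterion_utilisation(patient: PatientRecord, index: IndexEvent,
                          registry: CodeSetRegistry, config: OutcomeConfig,
                          which: str) -> bool:
    """Distinct encounter days in the window, optionally restricted to
    seizure-related-coded encounters, against the configured threshold."""
    if which == "seizure_related":
        days = {
            enc.date for enc in _window_encounters(patient, index, config)
            if registry.encounter_matches("seizure_related_utilisation", enc)}
        threshold = config.thresholds["seizure_utilisation_min_distinct_days"]
    elif which == "all":
        days = {enc.date
                for enc in _window_encounters(patient, index, config)}
        threshold = config.thresholds["all_utilisation_min_distinct_days"]
    else:
        raise ValueError(f"which must be 'seizure_related' or 'all', "
                         f"got {which!r}")
    return len(days) >= threshold


def criterion_inpatient(patient: PatientRecord, index: IndexEvent,
                        registry: CodeSetRegistry,
                        config: OutcomeConfig) -> bool:
    count = sum(
        1 for enc in _window_encounters(patient, index, config)
        if enc.setting == "inpatient"
        and registry.encounter_matches("seizure_related_utilisation", enc))
    return count >= config.thresholds["inpatient_min_admissions"]


def criterion_diagnostics(patient: PatientRecord, index: IndexEvent,
                          registry: CodeSetRegistry,
                          config: OutcomeConfig) -> bool:
    """Seizure-related diagnostic testing: EEG/imaging orders in the window
    on a day that also carries a seizure-related diagnosis."""
    seizure_days = {
        enc.date for enc in patient.encounters
        if registry.encounter_matches("seizure_related_utilisation", enc)}
    count = sum(
        1 for proc in patient.procedures
        if _in_window(proc.date, index, config)
        and registry.matches("diagnostic_testing", proc.code, proc.dialect)
        and proc.date in seizure_days)
    return count >= config.thresholds["diagnostics_min_count"]


def composite_label(patient: PatientRecord, index: IndexEvent,
                    registry: CodeSetRegistry,
                    config: OutcomeConfig | None = None) -> OutcomeLabel:
    """Evaluate all seven recurrence measures; composite is their OR."""
    config = config or OutcomeConfig()
    config.validate()
    fields = {
        "asm": criterion_asm(patient, index, registry, config),
        "status_epilepticus": criterion_status_epilepticus(
            patient, index, registry, config),
        "inpatient_seizure": criterion_inpatient(
            patient, index, registry, config),
        "seizure_utilisation": criterion_utilisation(
            patient, index, registry, config, "seizure_related"),
        "all_utilisation": (
            config.include_all_utilisation
            and criterion_utilisation(patient, index, registry, config, "all")),
        "diagnostics": criterion_diagnostics(patient, index, registry, config),
        "procedure": criterion_procedure(patient, index, registry, config),
    }
    return OutcomeLabel(patient_id=patient.patient_id, **fields,
                        composite=any(fields.values()))


def label_cohort(records: list[PatientRecord], cohort: pd.DataFrame,
                 registry: CodeSetRegistry,
                 config: OutcomeConfig | None = None) -> pd.DataFrame:
    """labels.csv content: one row of eight booleans per included patient."""
    from .cohort import find_index_event

    included = set(cohort.loc[cohort["included"], "patient_id"])
    rows = []
    for patient in records:
        if patient.patient_id not in included:
            continue
        index = find_index_event(patient, registry)
        label = composite_label(patient, index, registry, config)
        rows.append({"patient_id": label.patient_id,
                     **{f: getattr(label, f) for f in CRITERION_FIELDS},
                     "composite": label.composite})
    columns = ["patient_id", *CRITERION_FIELDS, "composite"]
    return pd.DataFrame(rows, columns=columns)


def write_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, index=False, lineterminator="\n")
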