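"""Patient-level longitudinal record model.

Dates are integer day offsets from a fixed epoch (2010-01-01) internally and
ISO-8601 calendar dates on disk.  Fixed-day window arithmetic is used
throughout: 1 week = 7 days, 1 year = 365 days, 2 years = 730 days.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

EPOCH = datetime.date(2010, 1, 1)

DAYS_PER_WEEK = 7
DAYS_PER_YEAR = 365
DAYS_TWO_YEARS = 730

SETTINGS = ("inpatient", "outpatient", "emergency")
NOTE_TYPES = (
    "neurology",
    "communication",
    "eeg_report",
    "mri_report",
    "ct_report",
    "discharge_summary",
)
DIALECTS = ("icd9", "icd10", "cpt")


def day_to_iso(day: int) -> str:
    """Integer day offset -> ISO-8601 calendar date string."""
    return (EPOCH + datetime.timedelta(days=int(day))).isoformat()


def iso_to_day(text: str) -> int:
    """ISO-8601 calendar date string -> integer day offset from the epoch."""
    return (datetime.date.fromisoformat(text) - EPOCH).days


@dataclass(frozen=True)
class DiagnosisCode:
    """A diagnosis code with its coding-system dialect tag."""

    code: str
    dialect: str  # "icd9" | "icd10"


@dataclass
class Encounter:
    """One visit: a date, a care setting, and an ordered diagnosis-code list.

    ``primary_code`` and ``admitting_code`` are *positions* into ``codes``;
    billing position matters for the status-epilepticus and procedure rules.
    """

    date: int
    setting: str
    codes: list[DiagnosisCode]
    primary_code: int = 0
    admitting_code: int | None = None

    def __post_init__(self):
        if not self.codes:
            raise ValueError("encounter codes must be nonempty")
        if not (0 <= self.primary_code < len(self.codes)):
            raise ValueError("primary_code index out of range")
        if self.admitting_code is not None and not (
            0 <= self.admitting_code < len(self.codes)
        ):
            raise ValueError("admitting_code index out of range")


@dataclass
class MedicationRecord:
    date: int
    drug: str
    source: str = "structured"  # "structured" | "note"


@dataclass
class ProcedureRecord:
    date: int
    code: str
    dialect: str = "cpt"


@dataclass
class Note:
    note_id: str
    patient_id: str
    date: int
    note_type: str
    text: str  # whitespace-delimited token sequence

    def __post_init__(self):
        if self.note_type not in NOTE_TYPES:
            raise ValueError(f"unknown note_type {self.note_type!r}")

    @property
    def tokens(self) -> list[str]:
        return self.text.split()


@dataclass
class CoveragePeriod:
    """Closed insurance-coverage date interval [start, end]."""

    start: int
    end: int


@dataclass
class PatientRecord:
    """One patient's demographics plus time-stamped clinical events.

    ``latent_recurrence`` is simulation ground truth; it is excluded from
    equality so that datasets round-trip identically whether or not the truth
    file was loaded, and it is never read by pipeline stages.
    """

    patient_id: str
    birth_date: int
    sex: str
    encounters: list[Encounter] = field(default_factory=list)
    medications: list[MedicationRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)
    notes: list[Note] = field(default_factory=list)
    coverage: list[CoveragePeriod] = field(default_factory=list)
    latent_recurrence: bool | None = field(default=None, compare=False)

    def validate(self) -> None:
        for enc in self.encounters:
            if enc.date < self.birth_date:
                raise ValueError(
                    f"{self.patient_id}: encounter before birth date"
                )
        dates = [e.date for e in self.encounters]
        if dates != sorted(dates):
            raise ValueError(f"{self.patient_id}: encounters not date-sorted")
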