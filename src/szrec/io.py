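"""Dataset directory serialization.

Layout (all UTF-8; CSVs RFC-4180; one JSON object per line in notes.jsonl):

    patients.csv     patient_id,birth_date,sex
    coverage.csv     patient_id,start,end
    encounters.csv   patient_id,date,setting,codes,primary_position,admitting_position
                     codes is a pipe-delimited ordered list of dialect:code pairs;
                     admitting_position is empty when absent (explicit null).
    medications.csv  patient_id,date,drug,source
    procedures.csv   patient_id,date,code,dialect
    notes.jsonl      {"date","note_id","note_type","patient_id","text"}
    truth.csv        patient_id,latent_recurrence  (simulation truth; written
                     separately and never read by pipeline stages)

Round-trip identity holds: read_dataset(write_dataset(x)) == x, including
code order and primary/admitting positions.
"""

from __future__ import annotations

import csv
import json
import os

from .errors import DatasetFormatError
from .records import (
    CoveragePeriod,
    DiagnosisCode,
    Encounter,
    MedicationRecord,
    Note,
    PatientRecord,
    ProcedureRecord,
    day_to_iso,
    iso_to_day,
)

_FILES = (
    "patients.csv",
    "coverage.csv",
    "encounters.csv",
    "medications.csv",
    "procedures.csv",
    "notes.jsonl",
)


def _encode_codes(codes: list[DiagnosisCode]) -> str:
    return "|".join(f"{c.dialect}:{c.code}" for c in codes)


def _decode_codes(text: str, file: str, line: int) -> list[DiagnosisCode]:
    out = []
    for item in text.split("|"):
        if ":" not in item:
            raise DatasetFormatError(file, line, "codes",
                                     f"malformed code entry {item!r}")
        dialect, code = item.split(":", 1)
        out.append(DiagnosisCode(code=code, dialect=dialect))
    return out


def write_dataset(records: list[PatientRecord], directory, *,
                  write_truth: bool = True) -> None:
    os.makedirs(directory, exist_ok=True)

    def _open(name):
        return open(os.path.join(directory, name), "w",
                    encoding="utf-8", newline="")

    with _open("patients.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "birth_date", "sex"])
        for r in records:
            w.writerow([r.patient_id, day_to_iso(r.birth_date), r.sex])

    with _open("coverage.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "start", "end"])
        for r in records:
            for c in r.coverage:
                w.writerow([r.patient_id, day_to_iso(c.start), day_to_iso(c.end)])

    with _open("encounters.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "setting", "codes",
                    "primary_position", "admitting_position"])
        for r in records:
            for e in r.encounters:
                w.writerow([
                    r.patient_id, day_to_iso(e.date), e.setting,
                    _encode_codes(e.codes), e.primary_code,
                    "" if e.admitting_code is None else e.admitting_code,
                ])

    with _open("medications.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "drug", "source"])
        for r in records:
            for m in r.medications:
                w.writerow([r.patient_id, day_to_iso(m.date), m.drug, m.source])

    with _open("procedures.csv") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "code", "dialect"])
        for r in records:
            for p in r.procedures:
                w.writerow([r.patient_id, day_to_iso(p.date), p.code, p.dialect])

    with open(os.path.join(directory, "notes.jsonl"), "w",
              encoding="utf-8") as fh:
        for r in records:
            for n in r.notes:
                fh.write(json.dumps({
                    "note_id": n.note_id,
                    "patient_id": n.patient_id,
                    "date": day_to_iso(n.date),
                    "note_type": n.note_type,
                    "text": n.text,
                }, sort_keys=True, ensure_ascii=True) + "\n")

    if write_truth:
        with _open("truth.csv") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "latent_recurrence"])
            for r in records:
                if r.latent_recurrence is not None:
                    w.writerow([r.patient_id, int(r.latent_recurrence)])


def _read_rows(path, expected_header):
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetFormatError(os.path.basename(path), 1, "header",
                                     "empty file") from None
        if header != list(expected_header):
            raise DatasetFormatError(os.path.basename(path), 1, "header",
                                     f"expected {expected_header}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(expected_header):
                raise DatasetFormatError(os.path.basename(path), lineno,
                                         "row", "wrong column count")
            yield lineno, row


def _parse_date(value, file, lineno, fieldname):
    try:
        return iso_to_day(value)
    except ValueError:
        raise DatasetFormatError(file, lineno, fieldname,
                                 f"bad ISO date {value!r}") from None


def read_dataset(directory) -> list[PatientRecord]:
    for name in _FILES:
        if not os.path.exists(os.path.join(directory, name)):
            raise DatasetFormatError(name, 0, "file", "missing dataset file")

    patients: dict[str, PatientRecord] = {}
    order: list[str] = []
    for lineno, (pid, birth, sex) in _read_rows(
            os.path.join(directory, "patients.csv"),
            ["patient_id", "birth_date", "sex"]):
        if pid in patients:
            raise DatasetFormatError("patients.csv", lineno, "patient_id",
                                     f"duplicate patient_id {pid!r}")
        patients[pid] = PatientRecord(
            patient_id=pid,
            birth_date=_parse_date(birth, "patients.csv", lineno, "birth_date"),
            sex=sex)
        order.append(pid)

    def _patient(pid, file, lineno):
        if pid not in patients:
            raise DatasetFormatError(file, lineno, "patient_id",
                                     f"unknown patient_id {pid!r}")
        return patients[pid]

    for lineno, (pid, start, end) in _read_rows(
            os.path.join(directory, "coverage.csv"),
            ["patient_id", "start", "end"]):
        _patient(pid, "coverage.csv", lineno).coverage.append(CoveragePeriod(
            start=_parse_date(start, "coverage.csv", lineno, "start"),
            end=_parse_date(end, "coverage.csv", lineno, "end")))

    for lineno, (pid, date, setting, codes, prim, adm) in _read_rows(
            os.path.join(directory, "encounters.csv"),
            ["patient_id", "date", "setting", "codes",
             "primary_position", "admitting_position"]):
        try:
            enc = Encounter(
                date=_parse_date(date, "encounters.csv", lineno, "date"),
                setting=setting,
                codes=_decode_codes(codes, "encounters.csv", lineno),
                primary_code=int(prim),
                admitting_code=None if adm == "" else int(adm))
        except ValueError as exc:
            raise DatasetFormatError("encounters.csv", lineno, "encounter",
                                     str(exc)) from None
        _patient(pid, "encounters.csv", lineno).encounters.append(enc)

    for lineno, (pid, date, drug, source) in _read_rows(
            os.path.join(directory, "medications.csv"),
            ["patient_id", "date", "drug", "source"]):
        _patient(pid, "medications.csv", lineno).medications.append(
            MedicationRecord(
                date=_parse_date(date, "medications.csv", lineno, "date"),
                drug=drug, source=source))

    for lineno, (pid, date, code, dialect) in _read_rows(
            os.path.join(directory, "procedures.csv"),
            ["patient_id", "date", "code", "dialect"]):
        _patient(pid, "procedures.csv", lineno).procedures.append(
            ProcedureRecord(
                date=_parse_date(date, "procedures.csv", lineno, "date"),
                code=code, dialect=dialect))

    notes_path = os.path.join(directory, "notes.jsonl")
    with open(notes_path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw:
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise DatasetFormatError("notes.jsonl", lineno, "json",
                                         str(exc)) from None
            for key in ("note_id", "patient_id", "date", "note_type", "text"):
                if key not in obj:
                    raise DatasetFormatError("notes.jsonl", lineno, key,
                                             "missing field")
            _patient(obj["patient_id"], "notes.jsonl", lineno).notes.append(
                Note(note_id=obj["note_id"], patient_id=obj["patient_id"],
                     date=_parse_date(obj["date"], "notes.jsonl", lineno,
                                      "date"),
                     note_type=obj["note_type"], text=obj["text"]))

    return [patients[pid] for pid in order]


def read_truth(directory) -> dict[str, bool]:
    """Load the latent-recurrence truth table (evaluation only)."""
    out = {}
    for lineno, (pid, flag) in _read_rows(
            os.path.join(directory, "truth.csv"),
            ["patient_id", "latent_recurrence"]):
        if flag not in ("0", "1"):
            raise DatasetFormatError("truth.csv", lineno, "latent_recurrence",
                                     f"expected 0/1, got {flag!r}")
        out[pid] = flag == "1"
    return out
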