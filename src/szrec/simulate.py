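"""Seeded synthetic pediatric EMR/claims cohort generator.

The generator emulates the temporal, coding and textual structure the
downstream stages assume: a pre-index healthy-care history, an index
seizure-like encounter before age 21, post-index seizure-related events whose
rates depend on a hidden (latent) recurrence status, antiseizure-medication
(ASM) prescriptions co-occurring with epilepsy-coded encounters, and clinical
notes whose token distributions carry a label-conditional shift.

Two tunable signal dials exist so the pipeline can be calibrated against an
exact null and a planted signal:

* ``structured_signal_strength`` scales label-conditional *pre-index* code
  rates (extra seizure-related codes on the index-day encounter plus a set of
  pre-index "risk marker" diagnoses).  At 0 the pre-index feature
  distributions of the two latent classes are identical by construction.
* ``text_signal_strength`` shifts the log-odds of prognosis-flavoured tokens
  in notes, with the largest shift in neurology notes and progressively
  smaller shifts in communications, discharge summaries and diagnostic
  reports, planting a recoverable gradient for the note-type ablation.

A configurable fraction of patients violates each cohort-inclusion criterion
so the filter logic is exercised.  Each patient draws from an independently
spawned child generator, so per-patient noise is reproducible and increasing
a signal dial moves each affected patient's event counts monotonically (the
counts are inverse-CDF transforms of per-patient uniforms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .records import (
    CoveragePeriod,
    DiagnosisCode,
    Encounter,
    MedicationRecord,
    Note,
    NOTE_TYPES,
    PatientRecord,
    ProcedureRecord,
)

# -- code pools ---------------------------------------------------------------

INDEX_CODES = [
    ("R56.9", "icd10"), ("780.39", "icd9"),
    ("G40.909", "icd10"), ("345.90", "icd9"),
]
INDEX_WEIGHTS = [0.45, 0.20, 0.25, 0.10]

EPILEPSY_CODES = [
    ("G40.909", "icd10"), ("G40.309", "icd10"), ("G40.109", "icd10"),
    ("345.90", "icd9"), ("345.10", "icd9"),
]
SEIZURE_RELATED_CODES = INDEX_CODES  # convulsions + epilepsy mixtures
SE_CODES = [("G40.901", "icd10"), ("345.3", "icd9")]

FILLER_CODES = [
    ("Z00.129", "icd10"), ("J06.9", "icd10"), ("J45.909", "icd10"),
    ("K21.9", "icd10"), ("L20.9", "icd10"), ("H66.90", "icd10"),
    ("R05", "icd10"), ("B34.9", "icd10"), ("Z23", "icd10"),
    ("S09.90XA", "icd10"), ("K59.00", "icd10"), ("N39.0", "icd10"),
    ("R50.9", "icd10"), ("J02.9", "icd10"), ("L50.9", "icd10"),
    ("V20.2", "icd9"), ("465.9", "icd9"), ("382.9", "icd9"),
    ("786.2", "icd9"), ("787.03", "icd9"),
]

# Long Zipf tail of generated filler diagnoses so the feature vocabulary has
# realistic width and the prevalence / top-k selection schemes have work to
# do.  Letters are chosen outside the seizure-related ICD-10 families.
FILLER_POOL = FILLER_CODES + [
    (f"{letter}{i}{j}.{k}", "icd10")
    for letter in "JKLMNPQ" for i in range(10) for j in range(10)
    for k in (j % 3,)
]
_ranks = np.arange(1, len(FILLER_POOL) + 1, dtype=float)
FILLER_WEIGHTS = (1.0 / _ranks ** 1.2)
FILLER_WEIGHTS /= FILLER_WEIGHTS.sum()
# Label-conditional pre-index "risk marker" diagnoses (none seizure-like).
MARKER_CODES = [
    ("R51.9", "icd10"), ("F88", "icd10"), ("R62.50", "icd10"),
    ("G93.40", "icd10"), ("R25.1", "icd10"), ("F90.9", "icd10"),
    ("R42", "icd10"), ("G43.909", "icd10"), ("R29.818", "icd10"),
    ("315.9", "icd9"),
]
PAIN_CODES = [("G89.29", "icd10"), ("M54.9", "icd10")]

DIAGNOSTIC_PROC_CODES = ["95819", "70551", "70450"]
EPILEPSY_PROC_CODES = ["95700", "61533"]

ASM_CHOICES = [
    "levetiracetam", "oxcarbazepine", "lamotrigine", "valproate",
    "topiramate", "ethosuximide", "clobazam", "lacosamide",
]
ASM_WEIGHTS = [0.40, 0.15, 0.12, 0.10, 0.08, 0.05, 0.05, 0.05]

# -- note text vocabulary -----------------------------------------------------

BACKGROUND_TOKENS = np.array("""
patient exam history presents mother father reports episode event seen
clinic follow up visit today well appearing alert oriented afebrile vitals
stable development appropriate review systems negative physical neurologic
cranial nerves intact strength tone gait reflexes symmetric sensation
pupils reactive fontanelle soft no acute distress sleep deprived awake
drowsy activity recorded background rhythm posterior dominant photic
stimulation hyperventilation performed tolerated study impression plan
discussed family return precautions counseled given education continue
monitor school daycare fever illness recent cold cough immunizations
current weight height percentile head circumference birth term delivery
uncomplicated milestones walking talking eating drinking denies vomiting
diarrhea rash headache dizziness vision hearing normal limits within
laboratory values unremarkable imaging obtained contrast without sequences
axial sagittal coronal ventricles midline shift mass effect hemorrhage
signal gray white matter differentiation preserved technique findings
clinical correlation recommended electrode placement international system
duration minutes recording quality adequate artifact movement chewing
""".split(), dtype=object)

PROGNOSIS_TOKENS = np.array(
    ["recurrence", "breakthrough", "refractory", "epileptiform", "spikes",
     "abnormal", "prolonged", "rescue", "clustering", "worsening"],
    dtype=object)
REASSURE_TOKENS = np.array(
    ["benign", "resolved", "reassuring", "isolated", "provoked",
     "singular", "uneventful", "improving"],
    dtype=object)

# Label-conditional log-odds shift per note type (multiplied by
# text_signal_strength); neurology notes carry the strongest planted signal,
# diagnostic reports the weakest.
NOTE_TYPE_SHIFT = {
    "neurology": 0.50,
    "communication": 0.25,
    "discharge_summary": 0.20,
    "eeg_report": 0.10,
    "mri_report": 0.05,
    "ct_report": 0.02,
}

_BASE_PROGNOSIS_P = 0.02
_BASE_REASSURE_P = 0.03
_BASE_MED_MENTION_P = 0.15

MED_SECTION_TEMPLATES = [
    "discharge medications : 1. levetiracetam 250 mg twice daily".split(),
    "medications : lev 500 mg daily".split(),
    "home medications : oxcarbazepine 300 mg nightly".split(),
    "medication changes : increase levetiracetam to 500 mg".split(),
]
NEGATED_MED_TOKENS = "parent denies taking levetiracetam at home".split()


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


# -- configuration ------------------------------------------------------------

def _default_event_rates() -> dict:
    return {
        "recurrent": {
            "epilepsy_days": 3.5,
            "other_days": 2.0,
            "se_prob": 0.20,
            "asm_prob": 0.55,
            "procedure_prob": 0.20,
            "diagnostics_prob": 0.45,
            "inpatient_frac": 0.30,
        },
        "nonrecurrent": {
            "epilepsy_days": 0.15,
            "other_days": 0.8,
            "se_prob": 0.01,
            "asm_prob": 0.025,
            "procedure_prob": 0.01,
            "diagnostics_prob": 0.03,
            "inpatient_frac": 0.10,
        },
    }


@dataclass
class SimConfig:
    """Generator settings; the defaults define the emulated study conditions.

    ``recurrence_prevalence`` is the latent (hidden) recurrence rate.  Under
    the default event rates the composite label fires for essentially all
    latent-recurrent patients and ~10% of latent-non-recurrent ones, so the
    default latent rates of 0.52 (EMR) and 0.59 (claims, see
    :func:`claims_default_config`) realize composite-label prevalences of
    about 0.57 and 0.63 respectively.
    """

    n_patients: int = 2000
    seed: int = 0
    recurrence_prevalence: float = 0.52
    modality: str = "emr"
    pre_index_history_days: dict = field(
        default_factory=lambda: {"median_days": 900.0, "sigma": 0.5})
    followup_days: dict = field(
        default_factory=lambda: {"min_days": 731, "max_days": 1000})
    event_rates: dict = field(default_factory=_default_event_rates)
    structured_signal_strength: float = 1.0
    text_signal_strength: float = 1.0
    # rates for the label-conditional structured signal (scaled by
    # structured_signal_strength for latent-recurrent patients)
    index_day_seizure_code_rate: float = 0.7
    pre_index_marker_rate: float = 1.0
    note_length_distribution: dict = field(
        default_factory=lambda: {"median_tokens": 1019.0,
                                 "frac_over_limit": 0.048,
                                 "limit_tokens": 4096,
                                 "min_tokens": 30})
    extra_notes_mean: float = 1.0
    infant_fraction: float = 0.16
    violation_fractions: dict = field(
        default_factory=lambda: {"no_index": 0.04, "index_age": 0.03,
                                 "prior_contact": 0.05, "followup": 0.05})

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        if not (0.0 <= self.recurrence_prevalence <= 1.0):
            raise ConfigurationError(
                "recurrence_prevalence must be a probability in [0, 1]")
        if self.modality not in ("emr", "claims"):
            raise ConfigurationError("modality must be 'emr' or 'claims'")
        if self.structured_signal_strength < 0:
            raise ConfigurationError(
                "structured_signal_strength must be nonnegative")
        if self.text_signal_strength < 0:
            raise ConfigurationError("text_signal_strength must be nonnegative")
        if self.index_day_seizure_code_rate < 0:
            raise ConfigurationError(
                "index_day_seizure_code_rate must be nonnegative")
        if self.pre_index_marker_rate < 0:
            raise ConfigurationError("pre_index_marker_rate must be nonnegative")
        if not (0.0 <= self.infant_fraction <= 1.0):
            raise ConfigurationError("infant_fraction must be in [0, 1]")
        for group, rates in self.event_rates.items():
            for key, value in rates.items():
                if value < 0:
                    raise ConfigurationError(
                        f"event_rates[{group}][{key}] must be nonnegative")
        total = 0.0
        for key, frac in self.violation_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(
                    f"violation_fractions[{key}] must be in [0, 1]")
            total += frac
        if total > 1.0:
            raise ConfigurationError("violation_fractions sum above 1")
        nl = self.note_length_distribution
        if not (0.0 < nl["frac_over_limit"] < 0.5):
            raise ConfigurationError(
                "note_length_distribution.frac_over_limit must be in (0, 0.5)")
        if nl["median_tokens"] <= 0 or nl["min_tokens"] <= 0:
            raise ConfigurationError(
                "note_length_distribution token counts must be positive")
        if self.followup_days["min_days"] <= 730:
            raise ConfigurationError(
                "followup_days.min_days must exceed 730 for included patients")


def claims_default_config(**overrides) -> SimConfig:
    """Claims-modality defaults: coverage periods, no note text, and a higher
    latent recurrence rate matching the nationwide-cohort composite mean."""
    cfg = SimConfig(modality="claims", recurrence_prevalence=0.59)
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


# -- note text ----------------------------------------------------------------

def _note_length_sigma(nl: dict) -> float:
    z = stats.norm.ppf(1.0 - nl["frac_over_limit"])
    return (math.log(nl["limit_tokens"]) - math.log(nl["median_tokens"])) / z


def _make_note_text(rng, latent: bool, note_type: str, n_tokens: int,
                    strength: float) -> str:
    sign = 1.0 if latent else -1.0
    shift = strength * NOTE_TYPE_SHIFT[note_type]
    p_prog = _sigmoid(_logit(_BASE_PROGNOSIS_P) + shift * sign)
    p_reas = _sigmoid(_logit(_BASE_REASSURE_P) - shift * sign)
    u = rng.random(n_tokens)
    tokens = BACKGROUND_TOKENS[rng.integers(0, len(BACKGROUND_TOKENS),
                                            n_tokens)].copy()
    prog_mask = u < p_prog
    reas_mask = (u >= p_prog) & (u < p_prog + p_reas)
    n_prog = int(prog_mask.sum())
    n_reas = int(reas_mask.sum())
    if n_prog:
        tokens[prog_mask] = PROGNOSIS_TOKENS[
            rng.integers(0, len(PROGNOSIS_TOKENS), n_prog)]
    if n_reas:
        tokens[reas_mask] = REASSURE_TOKENS[
            rng.integers(0, len(REASSURE_TOKENS), n_reas)]
    parts = list(tokens)

    # Note-only medication mentions (absent from structured data).
    p_med = _sigmoid(_logit(_BASE_MED_MENTION_P) + 0.5 * strength * sign)
    if rng.random() < p_med:
        parts.extend(MED_SECTION_TEMPLATES[
            rng.integers(0, len(MED_SECTION_TEMPLATES))])
    if rng.random() < 0.05:  # label-independent negated mention
        parts.extend(NEGATED_MED_TOKENS)
    return " ".join(parts)


# -- patient generation -------------------------------------------------------

def _dc(pair) -> DiagnosisCode:
    return DiagnosisCode(code=pair[0], dialect=pair[1])


def _choice(rng, pool, weights=None):
    idx = rng.choice(len(pool), p=weights)
    return pool[int(idx)]


def _scaled_count(rng, base_rate: float, latent: bool, strength: float) -> int:
    """Poisson count via inverse CDF so it is monotone in the signal dial."""
    lam = base_rate * (1.0 + strength) if latent else base_rate
    u = rng.random()
    if lam <= 0:
        return 0
    return int(stats.poisson.ppf(u, lam))


def _generate_patient(pid: str, rng, cfg: SimConfig) -> PatientRecord:
    vf = cfg.violation_fractions
    cats = ["none", "no_index", "index_age", "prior_contact", "followup"]
    probs = [1.0 - sum(vf.values()), vf["no_index"], vf["index_age"],
             vf["prior_contact"], vf["followup"]]
    cat = _choice(rng, cats, np.asarray(probs) / sum(probs))

    latent = bool(rng.random() < cfg.recurrence_prevalence)
    s = cfg.structured_signal_strength

    if cat == "index_age":
        age = int(rng.integers(21 * 365, 25 * 365))
        infant = False
    else:
        infant = bool(rng.random() < cfg.infant_fraction)
        age = int(rng.integers(60, 365)) if infant else int(
            rng.integers(400, 21 * 365))
    index_date = int(rng.integers(1100, 1601))
    birth = index_date - age
    sex = "M" if rng.random() < 0.55 else "F"

    encounters: list[Encounter] = []
    medications: list[MedicationRecord] = []
    procedures: list[ProcedureRecord] = []
    notes: list[Note] = []

    # --- pre-index history (first contact + extra visits) --------------------
    if cat == "prior_contact":
        lead = int(rng.integers(1, 7)) if infant else int(rng.integers(30, 201))
    elif infant:
        lead = int(rng.integers(7, max(8, min(age - 15, 300))))
    else:
        hist = cfg.pre_index_history_days
        lead = int(rng.lognormal(math.log(hist["median_days"]), hist["sigma"]))
        lead = min(max(lead, 366), age - 1)
    first_contact = index_date - lead
    encounters.append(Encounter(date=first_contact, setting="outpatient",
                                codes=[_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS))]))
    n_hist = int(rng.poisson(2.0))
    if first_contact < index_date - 7:
        for date in rng.integers(first_contact, index_date - 7, n_hist):
            encounters.append(Encounter(date=int(date), setting="outpatient",
                                        codes=[_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS))]))

    # --- pre-index risk markers (structured signal, part b) ------------------
    n_markers = _scaled_count(rng, cfg.pre_index_marker_rate, latent, s)
    lo = max(first_contact, index_date - 300)
    if lo < index_date - 8:
        for _ in range(n_markers):
            date = int(rng.integers(lo, index_date - 8))
            encounters.append(Encounter(date=date, setting="outpatient",
                                        codes=[_dc(_choice(rng, MARKER_CODES))]))

    # --- index encounter -----------------------------------------------------
    has_index = cat != "no_index"
    if has_index:
        codes = [_dc(_choice(rng, INDEX_CODES, INDEX_WEIGHTS))]
        # structured signal, part a: extra seizure-related codes on index day
        n_extra = _scaled_count(rng, cfg.index_day_seizure_code_rate, latent, s)
        for _ in range(n_extra):
            codes.append(_dc(_choice(rng, SEIZURE_RELATED_CODES)))
        if rng.random() < 0.3:
            codes.append(_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS)))
        setting = "emergency" if rng.random() < 0.5 else "outpatient"
        encounters.append(Encounter(date=index_date, setting=setting,
                                    codes=codes, primary_code=0))
    else:
        encounters.append(Encounter(date=index_date, setting="outpatient",
                                    codes=[_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS))]))

    # --- post-index events ---------------------------------------------------
    if has_index:
        rates = cfg.event_rates["recurrent" if latent else "nonrecurrent"]
        win_lo, win_hi = index_date + 8, index_date + 721

        if rng.random() < 0.15:  # event inside the 7-day blanking window
            encounters.append(Encounter(
                date=index_date + int(rng.integers(1, 8)),
                setting="emergency",
                codes=[_dc(_choice(rng, SEIZURE_RELATED_CODES))]))

        ep_dates = sorted({int(d) for d in rng.integers(
            win_lo, win_hi, rng.poisson(rates["epilepsy_days"]))})
        for date in ep_dates:
            codes = [_dc(_choice(rng, EPILEPSY_CODES))]
            if rng.random() < 0.3:
                codes.append(_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS)))
            if rng.random() < rates["inpatient_frac"]:
                setting = "inpatient"
            else:
                setting = "emergency" if rng.random() < 0.3 else "outpatient"
            encounters.append(Encounter(date=date, setting=setting,
                                        codes=codes, primary_code=0))

        for date in rng.integers(win_lo, win_hi,
                                 rng.poisson(rates["other_days"])):
            encounters.append(Encounter(date=int(date), setting="outpatient",
                                        codes=[_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS))]))

        if rng.random() < rates["se_prob"]:
            date = int(rng.integers(win_lo, win_hi))
            se = _dc(_choice(rng, SE_CODES))
            variant = rng.random()
            if variant < 0.6:  # SE code in primary position
                enc = Encounter(date=date, setting="inpatient",
                                codes=[se, _dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS))],
                                primary_code=0)
            elif variant < 0.9:  # SE buried, epilepsy-specific admitting code
                enc = Encounter(
                    date=date, setting="inpatient",
                    codes=[_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS)), se,
                           _dc(_choice(rng, EPILEPSY_CODES))],
                    primary_code=0, admitting_code=2)
            else:  # SE buried with filler primary: does not satisfy the rule
                enc = Encounter(date=date, setting="inpatient",
                                codes=[_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS)), se],
                                primary_code=0)
            encounters.append(enc)

        if rng.random() < rates["asm_prob"]:
            drug = _choice(rng, ASM_CHOICES, ASM_WEIGHTS)
            if ep_dates:
                date = ep_dates[int(rng.integers(0, len(ep_dates)))]
            else:
                date = int(rng.integers(win_lo, win_hi))
                encounters.append(Encounter(
                    date=date, setting="outpatient",
                    codes=[_dc(_choice(rng, EPILEPSY_CODES))]))
            medications.append(MedicationRecord(date=date, drug=drug))

        if rng.random() < 0.04:  # gabapentin for pain: must not fire the rule
            date = int(rng.integers(win_lo, win_hi))
            encounters.append(Encounter(date=date, setting="outpatient",
                                        codes=[_dc(_choice(rng, PAIN_CODES))]))
            medications.append(MedicationRecord(date=date, drug="gabapentin"))

        if rng.random() < rates["procedure_prob"]:
            date = int(rng.integers(win_lo, index_date + 700))
            encounters.append(Encounter(
                date=date, setting="inpatient",
                codes=[_dc(_choice(rng, EPILEPSY_CODES)),
                       _dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS))],
                primary_code=0))
            procedures.append(ProcedureRecord(
                date=date, code=_choice(rng, EPILEPSY_PROC_CODES)))
            if rng.random() < 0.85 and not any(d >= date + 7 for d in ep_dates):
                confirm = int(rng.integers(date + 7, max(date + 8, win_hi)))
                encounters.append(Encounter(
                    date=confirm, setting="outpatient",
                    codes=[_dc(_choice(rng, EPILEPSY_CODES))]))

        if rng.random() < rates["diagnostics_prob"]:
            date = int(rng.integers(win_lo, win_hi))
            procedures.append(ProcedureRecord(
                date=date, code=_choice(rng, DIAGNOSTIC_PROC_CODES)))
            encounters.append(Encounter(
                date=date, setting="outpatient",
                codes=[_dc(_choice(rng, SEIZURE_RELATED_CODES))]))

    # --- follow-up contact ---------------------------------------------------
    if cat != "followup":
        fu = cfg.followup_days
        encounters.append(Encounter(
            date=index_date + int(rng.integers(fu["min_days"],
                                               fu["max_days"] + 1)),
            setting="outpatient", codes=[_dc(_choice(rng, FILLER_POOL, FILLER_WEIGHTS))]))

    encounters.sort(key=lambda e: e.date)

    # --- coverage (claims modality) ------------------------------------------
    coverage: list[CoveragePeriod] = []
    if cfg.modality == "claims":
        start = encounters[0].date if cat == "prior_contact" else \
            encounters[0].date - 30
        end = encounters[-1].date if cat == "followup" else \
            encounters[-1].date + 30
        coverage.append(CoveragePeriod(start=start, end=end))

    # --- notes (EMR modality) ------------------------------------------------
    if cfg.modality == "emr":
        nl = cfg.note_length_distribution
        sigma = _note_length_sigma(nl)
        counter = 0

        def _add_note(note_type: str, date: int):
            nonlocal counter
            n_tok = int(rng.lognormal(math.log(nl["median_tokens"]), sigma))
            n_tok = max(nl["min_tokens"], min(n_tok, 8 * nl["limit_tokens"]))
            notes.append(Note(
                note_id=f"{pid}-N{counter:02d}", patient_id=pid,
                date=date, note_type=note_type,
                text=_make_note_text(rng, latent, note_type, n_tok,
                                     cfg.text_signal_strength)))
            counter += 1

        _add_note("neurology", index_date)  # >=1 note per index encounter
        other_types = [t for t in NOTE_TYPES if t != "neurology"]
        for _ in range(int(rng.poisson(cfg.extra_notes_mean))):
            date = index_date + int(rng.integers(-2, 7))
            _add_note(_choice(rng, other_types), max(date, birth))

    record = PatientRecord(
        patient_id=pid, birth_date=birth, sex=sex,
        encounters=encounters, medications=medications,
        procedures=procedures, notes=notes, coverage=coverage,
        latent_recurrence=latent)
    record.validate()
    return record


def generate_cohort(config: SimConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` synthetic patient records.

    Deterministic: the same config (including seed) yields byte-identical
    serialized output.
    """
    config.validate()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_patients)
    return [
        _generate_patient(f"P{i:06d}", np.random.default_rng(child), config)
        for i, child in enumerate(children)
    ]
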