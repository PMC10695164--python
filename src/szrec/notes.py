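"""Clinical-note path: chunking, medication extraction, pluggable note
scoring, margin-based aggregation, and the note-type ablation harness.

Long notes are split into overlapping windows (default 4096 tokens with a
512-token overlap; tokenization is whitespace splitting).  Chunk scores are
reduced to a note score, and note scores to a patient class, by the same
rule: keep the prediction with the largest margin from the 0.5 threshold —
a pseudo-confidence aggregation that trusts the most confident note.  Ties
(equal margins on opposite sides, or a score exactly at threshold) resolve
to the positive class: deterministic and clinically conservative.

The scorer is pluggable: anything with ``fit(texts, labels)`` and
``score_batch(texts) -> array in [0, 1]`` can stand in for the default
term-frequency linear model (where a fine-tuned long-context transformer
would plug in at production scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .codes import CodeSetRegistry
from .errors import ConfigurationError, ContractError, SingleClassError
from .evaluate import (
    EvalResult,
    auroc_only,
    compute_metrics,
    cv_interval,
    f1_score_only,
)
from .records import MedicationRecord, Note, NOTE_TYPES, PatientRecord

DEFAULT_THRESHOLD = 0.5


@dataclass
class ChunkingConfig:
    max_tokens: int = 4096
    overlap_tokens: int = 512

    def validate(self) -> None:
        if self.max_tokens <= 0:
            raise ConfigurationError("max_tokens must be positive")
        if not (0 <= self.overlap_tokens < self.max_tokens):
            raise ConfigurationError(
                "overlap_tokens must satisfy 0 <= overlap < max_tokens")

    @property
    def stride(self) -> int:
        return self.max_tokens - self.overlap_tokens


def chunk_spans(n_tokens: int, config: ChunkingConfig) -> list[tuple[int, int]]:
    """Half-open [start, end) windows covering every token index.

    A note at or under the limit is a single window.  Longer notes start
    windows at multiples of stride = max_tokens - overlap_tokens while the
    start is inside the note; consecutive full windows share exactly
    overlap_tokens tokens and the last window is truncated at the note end.
    """
    config.validate()
    if n_tokens <= 0:
        raise ValueError("token sequence must be nonempty")
    if n_tokens <= config.max_tokens:
        return [(0, n_tokens)]
    spans = []
    start = 0
    while start < n_tokens:
        spans.append((start, min(start + config.max_tokens, n_tokens)))
        start += config.stride
    return spans


def chunk_note(tokens, config: ChunkingConfig | None = None) -> list[list[str]]:
    config = config or ChunkingConfig()
    tokens = list(tokens)
    return [tokens[a:b] for a, b in chunk_spans(len(tokens), config)]


# -- rules-based medication extraction ---------------------------------------

SECTION_HEADERS = {
    "discharge_meds": ("discharge", "medications"),
    "history": ("home", "medications"),
    "history2": ("medication", "history"),
    "changes": ("medication", "changes"),
    "orders": ("medication", "orders"),
    "other_meds": ("medications",),
}
_HEADER_TO_SECTION = {
    "discharge_meds": "discharge_meds",
    "history": "history",
    "history2": "history",
    "changes": "changes",
    "orders": "orders",
    "other_meds": "other",
}
NEGATION_CUES = {"no", "denies", "not", "without", "discontinued", "stopped"}
NEGATION_WINDOW = 3  # tokens before a mention scanned for a cue
SECTION_SPAN = 40    # tokens after a header treated as the section body


@dataclass(frozen=True)
class MedicationMention:
    note_id: str
    surface: str
    drug: str
    drug_class: str
    negated: bool
    section: str  # history | changes | orders | discharge_meds | other


def _section_starts(tokens_lower: list[str]) -> list[tuple[int, str]]:
    starts = []
    for i, tok in enumerate(tokens_lower):
        for name, pattern in SECTION_HEADERS.items():
            span = tuple(tokens_lower[i:i + len(pattern)])
            if span == pattern:
                # longest match wins; skip bare "medications" inside a
                # two-token header matched at the previous position
                if name == "other_meds" and i > 0 and tokens_lower[i - 1] in (
                        "discharge", "home", "medication"):
                    continue
                starts.append((i, _HEADER_TO_SECTION[name]))
    return starts


def extract_medications(note: Note,
                        registry: CodeSetRegistry) -> list[MedicationMention]:
    """Lexicon matches with header-based sectioning and cue-based negation.

    Abbreviations normalize through the lexicon alias table (e.g. "LEV" ->
    levetiracetam).  A mention within NEGATION_WINDOW tokens after a negation
    cue is flagged negated; negated mentions are excluded from downstream ASM
    features by the harvesting helper.
    """
    tokens = note.tokens
    lower = [t.lower() for t in tokens]
    starts = _section_starts(lower)
    mentions = []
    for i, tok in enumerate(lower):
        drug = registry.resolve_drug(tok)
        if drug is None:
            continue
        section = "other"
        for start, name in starts:
            if start <= i <= start + SECTION_SPAN:
                section = name
        negated = any(
            lower[j] in NEGATION_CUES
            for j in range(max(0, i - NEGATION_WINDOW), i))
        entry = registry.asm_lexicon[drug]
        mentions.append(MedicationMention(
            note_id=note.note_id, surface=tokens[i], drug=drug,
            drug_class=entry.drug_class, negated=negated, section=section))
    return mentions


def harvest_note_medications(patient: PatientRecord,
                             registry: CodeSetRegistry) -> list[MedicationRecord]:
    """Non-negated note mentions as medication records (source='note'),
    deduplicated against same-day structured records for the same drug."""
    existing = {(m.date, m.drug.lower()) for m in patient.medications}
    out = []
    for note in patient.notes:
        for mention in extract_medications(note, registry):
            if mention.negated:
                continue
            key = (note.date, mention.drug)
            if key in existing:
                continue
            existing.add(key)
            out.append(MedicationRecord(date=note.date, drug=mention.drug,
                                        source="note"))
    return out


# -- note scoring -------------------------------------------------------------

@dataclass(frozen=True)
class NotePrediction:
    note_id: str
    patient_id: str
    score: float
    note_type: str


class HashCache:
    """Shared stateless text -> hashed-count-row cache.

    Hashing is label-free and row-independent, so sharing vectorized rows
    across CV folds cannot leak labels between folds; it only avoids
    re-tokenizing the same chunk text five times.
    """

    def __init__(self, n_features: int = 2 ** 15):
        from sklearn.feature_extraction.text import HashingVectorizer

        self._vectorizer = HashingVectorizer(
            n_features=n_features, alternate_sign=False, norm="l2",
            analyzer=str.split)
        self._rows: dict[str, sp.csr_matrix] = {}

    def transform(self, texts: list[str]) -> sp.csr_matrix:
        missing = [t for t in texts if t not in self._rows]
        if missing:
            matrix = self._vectorizer.transform(missing)
            for text, row in zip(missing, matrix):
                self._rows[text] = row
        if not texts:
            return self._vectorizer.transform([])
        return sp.vstack([self._rows[t] for t in texts], format="csr")


class TermFrequencyScorer:
    """Default note scorer: logistic regression over hashed term frequencies."""

    def __init__(self, seed: int = 0, n_features: int = 2 ** 15, C: float = 1.0,
                 cache: HashCache | None = None):
        from sklearn.linear_model import LogisticRegression

        self._cache = cache or HashCache(n_features)
        self._model = LogisticRegression(max_iter=1000, C=C,
                                         random_state=seed)

    def fit(self, texts: list[str], labels) -> "TermFrequencyScorer":
        y = np.asarray(labels, dtype=int)
        if len(np.unique(y)) < 2:
            raise SingleClassError("note scorer needs both classes to fit")
        self._model.fit(self._cache.transform(list(texts)), y)
        return self

    def score_batch(self, texts: list[str]) -> np.ndarray:
        return self._model.predict_proba(
            self._cache.transform(list(texts)))[:, 1]


class ConstantScorer:
    """Degenerate scorer for tests and calibration baselines."""

    def __init__(self, value: float = 0.5):
        self.value = value

    def fit(self, texts, labels):
        return self

    def score_batch(self, texts):
        return np.full(len(texts), self.value)


def margin_pick(scores, threshold: float = DEFAULT_THRESHOLD) -> int:
    """Index of the prediction with the largest |score - threshold|.

    Ties resolve toward the positive side, then toward the earliest
    prediction.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("empty prediction list")
    return max(range(len(scores)),
               key=lambda i: (abs(scores[i] - threshold),
                              scores[i] >= threshold,
                              -i))


def score_notes(notes: list[Note], labels: dict[str, bool], scorer,
                train_ids, config: ChunkingConfig | None = None
                ) -> list[NotePrediction]:
    """Fit the scorer on training patients' chunks, then score every note.

    Each note is chunked; chunk scores reduce to the note score by the
    largest-margin rule.  ``train_ids`` must cover every training patient and
    be disjoint from the ids evaluated downstream (asserted by the CV
    drivers).
    """
    config = config or ChunkingConfig()
    train_ids = set(train_ids)
    chunk_texts: list[str] = []
    note_slices: list[tuple[Note, int, int]] = []
    train_rows: list[int] = []
    train_labels: list[bool] = []
    for note in notes:
        tokens = note.tokens
        start = len(chunk_texts)
        if len(tokens) <= config.max_tokens:
            # single window: reuse the note text, skipping a re-join
            chunk_texts.append(note.text)
        else:
            chunk_texts.extend(
                " ".join(tokens[a:b])
                for a, b in chunk_spans(len(tokens), config))
        note_slices.append((note, start, len(chunk_texts)))
        if note.patient_id in train_ids:
            for row in range(start, len(chunk_texts)):
                train_rows.append(row)
                train_labels.append(labels[note.patient_id])

    scorer.fit([chunk_texts[i] for i in train_rows], train_labels)
    scores = np.asarray(scorer.score_batch(chunk_texts), dtype=float)
    if scores.shape != (len(chunk_texts),):
        raise ContractError("scorer returned wrong number of scores")
    if np.any((scores < 0) | (scores > 1)):
        raise ContractError("scorer returned scores outside [0, 1]")

    predictions = []
    for note, start, end in note_slices:
        chunk_scores = scores[start:end]
        best = margin_pick(chunk_scores)
        predictions.append(NotePrediction(
            note_id=note.note_id, patient_id=note.patient_id,
            score=float(chunk_scores[best]), note_type=note.note_type))
    return predictions


def aggregate_patient(predictions: list[NotePrediction],
                      threshold: float = DEFAULT_THRESHOLD
                      ) -> tuple[int, float, str]:
    """(class, margin, winning note id) from one patient's note predictions.

    The class follows the prediction farthest from the threshold
    (score >= threshold -> positive); invariant to prediction order and to
    duplicates of the winning prediction.
    """
    if not predictions:
        raise ValueError("empty prediction list")
    best = margin_pick([p.score for p in predictions], threshold)
    winner = predictions[best]
    cls = int(winner.score >= threshold)
    return cls, abs(winner.score - threshold), winner.note_id


def aggregate_patients(predictions: list[NotePrediction],
                       threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    by_patient: dict[str, list[NotePrediction]] = {}
    for pred in predictions:
        by_patient.setdefault(pred.patient_id, []).append(pred)
    rows = []
    for pid in sorted(by_patient):
        cls, margin, note_id = aggregate_patient(by_patient[pid], threshold)
        winner_score = next(p.score for p in by_patient[pid]
                            if p.note_id == note_id)
        rows.append({"patient_id": pid, "predicted_class": cls,
                     "margin": margin, "winning_note_id": note_id,
                     "score": winner_score})
    return pd.DataFrame(rows, columns=["patient_id", "predicted_class",
                                       "margin", "winning_note_id", "score"])


def select_scoring_notes(records: list[PatientRecord],
                         index_dates: dict[str, int],
                         max_days_after_index: int = 7) -> list[Note]:
    """Notes eligible for scoring: dated no later than index + blanking, to
    keep outcome-window documentation out of the predictors."""
    out = []
    for patient in records:
        index_date = index_dates.get(patient.patient_id)
        if index_date is None:
            continue
        out.extend(n for n in patient.notes
                   if n.date <= index_date + max_days_after_index)
    return out


def cross_validate_notes(notes: list[Note], labels: dict[str, bool],
                         folds: list[list[str]], scorer_factory,
                         config: ChunkingConfig | None = None,
                         name: str = "notes", n_boot: int = 1000,
                         boot_seed: int = 0) -> EvalResult:
    """Patient-level CV of the note pipeline; pooled margin-aggregated
    patient scores feed the metrics.  Patients with no eligible notes are
    excluded from evaluation and counted."""
    config = config or ChunkingConfig()
    patients_with_notes = {n.patient_id for n in notes}
    all_ids = [pid for fold in folds for pid in fold]
    n_excluded = sum(1 for pid in all_ids if pid not in patients_with_notes)

    pooled: dict[str, float] = {}
    fold_map: dict[str, int] = {}
    per_fold = []
    for fold_idx, test_ids in enumerate(folds):
        test_set = {pid for pid in test_ids if pid in patients_with_notes}
        train_set = {pid for f, fold in enumerate(folds) if f != fold_idx
                     for pid in fold if pid in patients_with_notes}
        if train_set & test_set:
            raise AssertionError("leakage: fold overlap")
        fold_notes = [n for n in notes
                      if n.patient_id in train_set | test_set]
        preds = score_notes(fold_notes, labels, scorer_factory(fold_idx),
                            train_set, config)
        test_preds = [p for p in preds if p.patient_id in test_set]
        agg = aggregate_patients(test_preds)
        y_test, s_test = [], []
        for _, row in agg.iterrows():
            pooled[row["patient_id"]] = row["score"]
            fold_map[row["patient_id"]] = fold_idx
            y_test.append(labels[row["patient_id"]])
            s_test.append(row["score"])
        try:
            fold_f1, fold_auroc = compute_metrics(y_test, s_test)
        except SingleClassError:
            fold_f1 = fold_auroc = float("nan")
        per_fold.append({"fold": fold_idx, "n": len(y_test),
                         "f1": fold_f1, "auroc": fold_auroc})

    eval_ids = [pid for pid in all_ids if pid in pooled]
    y = np.array([labels[pid] for pid in eval_ids], dtype=bool)
    s = np.array([pooled[pid] for pid in eval_ids])
    f1, auroc = compute_metrics(y, s)
    k = len(folds)
    return EvalResult(
        name=name, n_patients=len(eval_ids), f1=f1, auroc=auroc,
        f1_ci=cv_interval(y, s, f1_score_only,
                          [f["f1"] for f in per_fold], k, n_boot, boot_seed),
        auroc_ci=cv_interval(y, s, auroc_only,
                             [f["auroc"] for f in per_fold], k, n_boot,
                             boot_seed),
        per_fold=per_fold, fold_map=fold_map, seed=boot_seed,
        n_excluded=n_excluded)


NOTE_TYPE_GROUPS = tuple(NOTE_TYPES) + ("all",)


def ablate_by_note_type(notes: list[Note], labels: dict[str, bool],
                        folds: list[list[str]], scorer_factory,
                        config: ChunkingConfig | None = None,
                        n_boot: int = 1000,
                        boot_seed: int = 0) -> pd.DataFrame:
    """Re-run the full score+aggregate+evaluate path restricted to each note
    type, plus 'all'.  Absent groups are reported with n_patients 0."""
    rows = []
    results: dict[str, EvalResult | None] = {}
    for group in NOTE_TYPE_GROUPS:
        group_notes = notes if group == "all" else [
            n for n in notes if n.note_type == group]
        if not group_notes:
            results[group] = None
            rows.append({"note_type": group, "n_patients": 0, "n_excluded":
                         sum(len(f) for f in folds), "f1": float("nan"),
                         "auroc": float("nan"), "auroc_lo": float("nan"),
                         "auroc_hi": float("nan")})
            continue
        result = cross_validate_notes(
            group_notes, labels, folds, scorer_factory, config,
            name=f"notes[{group}]", n_boot=n_boot, boot_seed=boot_seed)
        results[group] = result
        rows.append({"note_type": group, "n_patients": result.n_patients,
                     "n_excluded": result.n_excluded, "f1": result.f1,
                     "auroc": result.auroc,
                     "auroc_lo": result.auroc_ci.lower,
                     "auroc_hi": result.auroc_ci.upper})
    table = pd.DataFrame(rows, columns=["note_type", "n_patients",
                                        "n_excluded", "f1", "auroc",
                                        "auroc_lo", "auroc_hi"])
    table.attrs["results"] = results
    return table
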