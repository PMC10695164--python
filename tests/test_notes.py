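import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from szrec.cohort import build_cohort, index_events
from szrec.errors import ConfigurationError, ContractError
from szrec.evaluate import compute_metrics, make_folds
from szrec.notes import (
    ChunkingConfig,
    ConstantScorer,
    HashCache,
    NotePrediction,
    TermFrequencyScorer,
    aggregate_patient,
    chunk_note,
    chunk_spans,
    extract_medications,
    score_notes,
    select_scoring_notes,
)
from szrec.outcomes import label_cohort
from szrec.records import Note
from szrec.simulate import SimConfig, generate_cohort

from _oracles import oracle_margin_pick


def _note(text, note_type="neurology", pid="P", nid="N0"):
    return Note(note_id=nid, patient_id=pid, date=0, note_type=note_type,
                text=text)


# -- chunking -----------------------------------------------------------------

@pytest.mark.parametrize("n,starts", [
    (4000, [0]),
    (4096, [0]),
    (4097, [0, 3584]),
    (5000, [0, 3584]),
    (8192, [0, 3584, 7168]),
    (12288, [0, 3584, 7168, 10752]),
])
def test_chunk_starts_follow_stride(n, starts):
    spans = chunk_spans(n, ChunkingConfig())
    assert [a for a, _ in spans] == starts
    assert spans[-1][1] == n  # tail covered
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        assert b1 - a2 == 512  # consecutive windows share exactly the overlap
        assert b1 - a1 <= 4096 and b2 - a2 <= 4096


def test_chunk_windows_reconstruct_original():
    tokens = [f"t{i}" for i in range(9000)]
    cfg = ChunkingConfig()
    windows = chunk_note(tokens, cfg)
    rebuilt = list(windows[0])
    for w in windows[1:]:
        rebuilt.extend(w[cfg.overlap_tokens:])
    assert rebuilt == tokens


def test_chunk_empty_and_bad_config():
    with pytest.raises(ValueError):
        chunk_spans(0, ChunkingConfig())
    with pytest.raises(ConfigurationError):
        chunk_spans(10, ChunkingConfig(max_tokens=100, overlap_tokens=100))


@settings(derandomize=True, max_examples=50)
@given(st.integers(min_value=1, max_value=30000))
def test_chunk_full_coverage_property(n):
    spans = chunk_spans(n, ChunkingConfig())
    covered = set()
    for a, b in spans:
        assert 0 <= a < b <= n
        covered.update(range(a, b) if b - a < 5000 else [a, b - 1])
    assert spans[0][0] == 0 and spans[-1][1] == n


# -- medication extraction ----------------------------------------------------

def test_discharge_section_mention(registry):
    note = _note("plan stable discharge medications : 1. levetiracetam "
                 "250 mg BID follow up")
    (m,) = extract_medications(note, registry)
    assert (m.drug, m.section, m.negated) == ("levetiracetam",
                                              "discharge_meds", False)
    assert m.drug_class == "asm"


def test_negation_cue_flags_mention(registry):
    note = _note("mother denies taking levetiracetam at home")
    (m,) = extract_medications(note, registry)
    assert m.negated


def test_abbreviation_normalizes(registry):
    note = _note("medications : LEV 500 mg daily")
    (m,) = extract_medications(note, registry)
    assert m.drug == "levetiracetam"
    assert m.surface == "LEV"
    assert m.section == "other"


def test_unknown_tokens_ignored(registry):
    note = _note("unremarkable exam no acute findings")
    assert extract_medications(note, registry) == []


# -- aggregation --------------------------------------------------------------

def _preds(scores):
    return [NotePrediction(note_id=f"n{i}", patient_id="P", score=s,
                           note_type="neurology")
            for i, s in enumerate(scores)]


@pytest.mark.parametrize("scores,expected", [
    ([0.9, 0.4], (1, 0.4, "n0")),
    ([0.6, 0.05], (0, 0.45, "n1")),
    ([0.5], (1, 0.0, "n0")),      # exactly at threshold -> positive
    ([0.4, 0.6], (1, 0.1, "n1")),  # margin tie across sides -> positive
])
def test_margin_aggregation_examples(scores, expected):
    cls, margin, nid = aggregate_patient(_preds(scores))
    assert (cls, pytest.approx(margin), nid) == expected


def test_aggregation_order_and_duplicate_invariance():
    preds = _preds([0.2, 0.9, 0.55])
    base = aggregate_patient(preds)[:2]
    assert aggregate_patient(preds[::-1])[:2] == base
    winner = max(preds, key=lambda p: abs(p.score - 0.5))
    assert aggregate_patient(preds + [winner])[:2] == base


def test_empty_predictions_rejected():
    with pytest.raises(ValueError):
        aggregate_patient([])


def test_aggregation_matches_bruteforce_10000():
    """Largest-margin aggregation equals brute-force argmax of |s - 0.5| on
    10 000 random prediction sets, including planted tie cases."""
    rng = np.random.default_rng(12)
    for trial in range(10_000):
        n = int(rng.integers(1, 8))
        scores = np.round(rng.random(n), 2)  # rounding plants exact ties
        cls, margin, nid = aggregate_patient(_preds(list(scores)))
        ocls, omargin, oi = oracle_margin_pick(list(scores))
        assert (cls, nid) == (ocls, f"n{oi}"), scores
        assert margin == pytest.approx(omargin)


# -- scoring ------------------------------------------------------------------

def test_constant_scorer_gives_constant_note_scores():
    notes = [_note("alpha beta", pid="A", nid="n1"),
             _note("gamma " * 5000, pid="B", nid="n2")]
    preds = score_notes(notes, {"A": True, "B": False}, ConstantScorer(0.5),
                        train_ids={"A", "B"})
    assert [p.score for p in preds] == [0.5, 0.5]


def test_out_of_range_scorer_rejected():
    notes = [_note("alpha beta", pid="A")]
    with pytest.raises(ContractError):
        score_notes(notes, {"A": True}, ConstantScorer(1.5), train_ids=set())


def test_chunk_scores_reduce_by_margin_rule():
    """A two-chunk note takes the more extreme chunk's score."""

    class ScriptedScorer:
        def fit(self, texts, labels):
            return self

        def score_batch(self, texts):
            return np.array([0.9, 0.45][:len(texts)])

    long_note = _note(" ".join(f"t{i}" for i in range(5000)), pid="A")
    (pred,) = score_notes([long_note], {"A": True}, ScriptedScorer(),
                          train_ids=set())
    assert pred.score == 0.9


def test_planted_signal_beats_permutation_null(registry):
    """On synthetic notes with planted token signal the default scorer's
    held-out note-level AUROC exceeds the permutation-null 95% band."""
    records = generate_cohort(SimConfig(n_patients=300, seed=9,
                                        text_signal_strength=2.0))
    cohort = build_cohort(records, registry, "emr")
    labels_df = label_cohort(records, cohort, registry)
    y = dict(zip(labels_df["patient_id"], labels_df["composite"]))
    idx = {p: e.index_date for p, e in index_events(records, registry).items()}
    notes = select_scoring_notes(
        [r for r in records if r.patient_id in y], idx)
    folds = make_folds(sorted(y), 5, seed=0, labels=y)
    train = {p for f in folds[1:] for p in f}
    test = set(folds[0])
    cache = HashCache()
    preds = score_notes(notes, y, TermFrequencyScorer(seed=0, cache=cache),
                        train)
    test_preds = [p for p in preds if p.patient_id in test]
    yy = np.array([y[p.patient_id] for p in test_preds])
    ss = np.array([p.score for p in test_preds])
    _, auroc = compute_metrics(yy, ss)
    rng = np.random.default_rng(0)
    null = []
    for _ in range(200):
        perm = rng.permutation(yy)
        null.append(compute_metrics(perm, ss)[1])
    assert auroc > np.quantile(null, 0.975)


def test_fold_hygiene_assertion():
    """No patient may appear in both fit and score sets of a fold."""
    from szrec.notes import cross_validate_notes

    notes = [_note("a b c", pid=p, nid=f"n{p}") for p in "ABCD"]
    labels = {"A": True, "B": False, "C": True, "D": False}
    overlapping = [["A", "B"], ["B", "C", "D"]]  # B in two folds
    with pytest.raises(AssertionError, match="leakage"):
        cross_validate_notes(notes, labels, overlapping,
                             lambda f: ConstantScorer(0.5), n_boot=10)
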