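import math

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from szrec.errors import ConfigurationError, ContractError
from szrec.features import (
    FeatureVocabulary,
    chi2_scores,
    extract_code_counts,
    normalize_counts,
    select_features,
)
from szrec.records import MedicationRecord, PatientRecord, ProcedureRecord

from conftest import enc, FILLER

IDX = 1000


def test_lookback_window_boundaries():
    """[index - 365, index] inclusive: the index day counts, day -366 not."""
    p = PatientRecord("X", birth_date=0, sex="F", encounters=[
        enc(IDX - 366, [("J45.909", "icd10")]),
        enc(IDX - 365, [("K21.9", "icd10")]),
        enc(IDX, [("G40.9", "icd10")]),
    ], medications=[MedicationRecord(date=IDX - 100, drug="Levetiracetam")],
        procedures=[ProcedureRecord(date=IDX - 10, code="95819")])
    counts = extract_code_counts(p, IDX)
    assert "dx:icd10:J45909" not in counts
    assert counts["dx:icd10:K219"] == 1
    assert counts["dx:icd10:G409"] == 1
    assert counts["rx:levetiracetam"] == 1
    assert counts["px:cpt:95819"] == 1


def test_no_events_gives_empty_map():
    p = PatientRecord("X", birth_date=0, sex="F", encounters=[])
    assert extract_code_counts(p, IDX) == {}


def test_log_normalization_closed_forms():
    values = normalize_counts({"a": 0, "b": 1, "c": 10})
    assert "a" not in values  # zero count -> value 0, stored sparsely
    assert values["b"] == pytest.approx(math.log(2), abs=1e-4)
    assert values["c"] == 1.0  # clipped


@settings(derandomize=True, max_examples=60)
@given(st.integers(min_value=0, max_value=1000),
       st.integers(min_value=0, max_value=1000))
def test_normalization_monotone_and_bounded(a, b):
    va = normalize_counts({"f": a}).get("f", 0.0)
    vb = normalize_counts({"f": b}).get("f", 0.0)
    assert 0.0 <= va <= 1.0
    if a <= b:
        assert va <= vb


def test_negative_count_rejected():
    with pytest.raises(ContractError):
        normalize_counts({"f": -1})


def test_vocabulary_fixed_order_and_unknown_drop():
    vocab = FeatureVocabulary.fit([{"b": 1}, {"a": 2}])
    assert vocab.ids == ["a", "b"]
    x = vocab.transform([{"a": 1, "zz": 5}])
    assert x.shape == (1, 2)
    assert x[0, 0] == pytest.approx(math.log(2))
    assert x[0, 1] == 0.0


def test_mapping_groups_codes():
    mapping = {"dx:icd10:G409": "phecode:345", "dx:icd10:G40909": "phecode:345"}
    vocab = FeatureVocabulary.fit(
        [{"dx:icd10:G409": 1, "dx:icd10:G40909": 1}], mapping=mapping)
    assert vocab.ids == ["phecode:345"]
    x = vocab.transform([{"dx:icd10:G409": 1, "dx:icd10:G40909": 1}])
    assert x[0, 0] == 1.0  # grouped count 2 -> clipped


def test_prevalence_selection_threshold():
    # feature 0 present in 1/200 rows (0.5%), feature 1 in 5/200
    rows = [{"rare": 1, "common": 1}] + [{"common": 1}] * 4 + [{}] * 195
    vocab = FeatureVocabulary.fit(rows)
    x = vocab.transform(rows)
    mask = select_features(x, np.zeros(200, dtype=bool), "prevalence", 0.01)
    assert dict(zip(vocab.ids, mask)) == {"common": True, "rare": False}


def test_chi2_ranks_concordant_feature_first():
    labels = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
    concordant = labels.astype(float)
    noise = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
    x = sp.csr_matrix(np.column_stack([noise, concordant]))
    mask = select_features(x, labels, "chi2", 1)
    assert mask.tolist() == [False, True]


def test_chi2_matches_contingency_oracle():
    rng = np.random.default_rng(9)
    presence = rng.random((120, 30)) < 0.3
    labels = rng.random(120) < 0.5
    scores = chi2_scores(presence, labels)
    for j in range(30):
        table = np.array([
            [np.sum(presence[labels, j]), np.sum(~presence[labels, j])],
            [np.sum(presence[~labels, j]), np.sum(~presence[~labels, j])],
        ])
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            expected = 0.0
        else:
            expected = chi2_contingency(table, correction=False)[0]
        assert scores[j] == pytest.approx(expected, abs=1e-9)


def test_chi2_cap_at_available_features():
    rng = np.random.default_rng(1)
    x = sp.csr_matrix((rng.random((50, 20)) < 0.4).astype(float))
    labels = rng.random(50) < 0.5
    mask = select_features(x, labels, "chi2", 500)
    assert mask.all()  # fewer features than requested -> keep all


def test_selection_param_validation():
    x = sp.csr_matrix(np.ones((4, 2)))
    y = np.array([1, 0, 1, 0], dtype=bool)
    with pytest.raises(ConfigurationError):
        select_features(x, y, "prevalence", 0.0)
    with pytest.raises(ConfigurationError):
        select_features(x, y, "chi2", 0)
    with pytest.raises(ConfigurationError):
        select_features(x, y, "lasso", 1)


def test_mask_changes_dimensionality_not_values():
    rows = [{"a": 1, "b": 2}, {"b": 1}]
    vocab = FeatureVocabulary.fit(rows)
    x = vocab.transform(rows)
    mask = np.array([False, True])
    sub = x[:, mask]
    assert sub.shape == (2, 1)
    assert np.allclose(sub.toarray()[:, 0], x.toarray()[:, 1])
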