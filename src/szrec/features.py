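"""Structured-data design matrix: pre-index code counts, log-normalization,
and the two feature-selection schemes.

Each patient is a vector of counts of every observed code in the year before
the index event, inclusive of the index day itself: window
``[index - 365, index]``.  Diagnoses, medications and procedures are
namespaced (``dx:``, ``rx:``, ``px:``).  Counts are squashed with
``min(ln(count + 1), 1)``: absent -> 0, one occurrence -> ln 2 ~ 0.693, two
or more -> 1.  The natural log is used; with base e the clip engages at two
occurrences, preserving a three-level signal while discounting repeat
billing.

Selection is fitted on training rows only: either keep features nonzero in at
least a given fraction of training patients (prevalence scheme), or keep the
top-k features by the one-degree-of-freedom chi-square statistic on
presence/absence against the label (chi2 scheme, no continuity correction,
ties broken by vocabulary order).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .codes import normalize_code
from .errors import ConfigurationError, ContractError
from .records import DAYS_PER_YEAR, PatientRecord


def extract_code_counts(patient: PatientRecord, index_date: int,
                        lookback_days: int = DAYS_PER_YEAR) -> dict[str, int]:
    """Counts of each observed code in [index - lookback, index] inclusive."""
    counts: dict[str, int] = {}

    def bump(key):
        counts[key] = counts.get(key, 0) + 1

    lo = index_date - lookback_days
    for enc in patient.encounters:
        if lo <= enc.date <= index_date:
            for code in enc.codes:
                bump(f"dx:{code.dialect}:{normalize_code(code.code)}")
    for med in patient.medications:
        if lo <= med.date <= index_date:
            bump(f"rx:{med.drug.lower()}")
    for proc in patient.procedures:
        if lo <= proc.date <= index_date:
            bump(f"px:{proc.dialect}:{normalize_code(proc.code)}")
    return counts


def normalize_counts(counts: dict[str, int]) -> dict[str, float]:
    """value = min(ln(count + 1), 1); monotone nondecreasing, bounded [0, 1]."""
    out = {}
    for key, count in counts.items():
        if count < 0:
            raise ContractError(f"negative count for feature {key!r}")
        if count:
            out[key] = min(math.log(count + 1), 1.0)
    return out


@dataclass
class FeatureVocabulary:
    """Ordered feature ids, optionally grouped through a code->group mapping
    (e.g. an ICD->PheCode table).  The default identity mapping keeps raw
    codes.  Order is fixed at fit time and reused at transform time; unseen
    ids are dropped at transform."""

    ids: list[str] = field(default_factory=list)
    mapping: dict[str, str] | None = None

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ConfigurationError("feature ids must be unique")
        self._index = {fid: i for i, fid in enumerate(self.ids)}

    def _map(self, fid: str) -> str:
        return self.mapping.get(fid, fid) if self.mapping else fid

    def map_counts(self, counts: dict[str, int]) -> dict[str, int]:
        out: dict[str, int] = {}
        for fid, count in counts.items():
            gid = self._map(fid)
            out[gid] = out.get(gid, 0) + count
        return out

    @classmethod
    def fit(cls, count_maps: list[dict[str, int]],
            mapping: dict[str, str] | None = None) -> "FeatureVocabulary":
        vocab = cls(ids=[], mapping=mapping)
        seen = set()
        for counts in count_maps:
            seen.update(vocab.map_counts(counts))
        return cls(ids=sorted(seen), mapping=mapping)

    def transform(self, count_maps: list[dict[str, int]]) -> sp.csr_matrix:
        """Rows of normalized values aligned to the vocabulary."""
        indptr = [0]
        indices: list[int] = []
        data: list[float] = []
        for counts in count_maps:
            values = normalize_counts(self.map_counts(counts))
            cols = sorted(self._index[f] for f in values if f in self._index)
            indices.extend(cols)
            data.extend(values[self.ids[c]] for c in cols)
            indptr.append(len(indices))
        return sp.csr_matrix(
            (np.asarray(data), np.asarray(indices, dtype=np.int32),
             np.asarray(indptr, dtype=np.int32)),
            shape=(len(count_maps), len(self.ids)))


def chi2_scores(presence: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-dof chi-square per feature from the 2x2 presence/label table,
    no continuity correction; degenerate margins score 0."""
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    n1 = int(labels.sum())
    n0 = n - n1
    pres = presence.astype(np.float64)
    a = pres[labels].sum(axis=0)          # present & positive
    c = pres[~labels].sum(axis=0)         # present & negative
    b = n1 - a
    d = n0 - c
    with np.errstate(divide="ignore", invalid="ignore"):
        num = n * (a * d - b * c) ** 2
        den = (a + b) * (c + d) * (a + c) * (b + d)
        scores = np.where(den > 0, num / den, 0.0)
    return scores


def select_features(matrix: sp.spmatrix, labels: np.ndarray, scheme: str,
                    param: float | int) -> np.ndarray:
    """Boolean keep-mask over the vocabulary, fitted on training rows only."""
    matrix = sp.csr_matrix(matrix)
    n_rows, n_features = matrix.shape
    if scheme == "prevalence":
        if not (0.0 < float(param) <= 1.0):
            raise ConfigurationError(
                "prevalence param must be a fraction in (0, 1]")
        col_nnz = np.bincount(matrix.indices, minlength=n_features)
        return col_nnz >= float(param) * n_rows
    if scheme == "chi2":
        k = int(param)
        if k < 1:
            raise ConfigurationError("chi2 param must be a positive integer")
        presence = np.asarray((matrix > 0).todense())
        scores = chi2_scores(presence, labels)
        order = np.argsort(-scores, kind="stable")  # ties: vocabulary order
        keep = order[:min(k, n_features)]
        mask = np.zeros(n_features, dtype=bool)
        mask[keep] = True
        return mask
    raise ConfigurationError(f"unknown selection scheme {scheme!r}")


def write_vocabulary(vocab: FeatureVocabulary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fid in vocab.ids:
            fh.write(fid + "\n")


def write_mask(mask: np.ndarray, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for bit in mask:
            fh.write(f"{int(bit)}\n")
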