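"""Classifiers, cross-validation protocol, metrics and bootstrap CIs.

Five-fold patient-level cross-validation: each fold is the held-out 20%
once, assignment seed-shuffled.  Metrics are computed from first principles:
F1 as the harmonic mean of precision and recall at a 0.5 threshold, AUROC as
the tie-aware Mann-Whitney statistic over all positive/negative score pairs.
95% CIs come from percentile bootstrap over patients (1000 resamples by
default); resamples collapsing to a single class are redrawn and counted.

Two baseline families mirror common structured-EHR practice: elastic-net
logistic regression with class balancing, and gradient-boosted trees with
500 estimators and L1/L2 regularization of 0.1 (other settings default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .errors import ConfigurationError, SingleClassError
from .features import FeatureVocabulary, select_features

MODEL_FAMILIES = ("elasticnet_logistic", "gradient_boosted_trees")


@dataclass
class ModelSpec:
    family: str = "elasticnet_logistic"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in MODEL_FAMILIES:
            raise ConfigurationError(
                f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")


def build_estimator(spec: ModelSpec):
    if spec.family == "elasticnet_logistic":
        from sklearn.linear_model import LogisticRegression

        params = {"solver": "saga", "l1_ratio": 0.5,
                  "class_weight": "balanced", "max_iter": 2000,
                  "random_state": spec.seed}
        params.update(spec.params)
        return LogisticRegression(**params)
    from xgboost import XGBClassifier

    params = {"n_estimators": 500, "reg_lambda": 0.1, "reg_alpha": 0.1,
              "tree_method": "hist", "n_jobs": 1,
              "random_state": spec.seed}
    params.update(spec.params)
    return XGBClassifier(**params)


def fit_predict(spec: ModelSpec, train_matrix, train_labels,
                test_matrix) -> np.ndarray:
    """Probability-scale scores for the test rows; deterministic given seed."""
    y = np.asarray(train_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise SingleClassError(
            "training labels contain a single class; cannot fit")
    model = build_estimator(spec)
    model.fit(train_matrix, y)
    return model.predict_proba(test_matrix)[:, 1]


def make_folds(patient_ids, k: int = 5, seed: int = 0,
               labels: dict | None = None) -> list[list[str]]:
    """k disjoint patient-level test folds of near-equal size (diff <= 1).

    With ``labels`` the assignment is class-stratified (per-class counts per
    fold also differ by at most 1).  Stratification keeps the class mix of
    every training fold equal to its test fold; without it, pooled
    cross-validated scores acquire a small pessimistic bias because a test
    fold rich in positives necessarily trains on a positive-poor remainder.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("patient ids must be unique")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of patients {len(ids)}")
    rng = np.random.default_rng(seed)
    if labels is None:
        order = rng.permutation(sorted(ids))
    else:
        pos = rng.permutation(sorted(p for p in ids if labels[p]))
        neg = rng.permutation(sorted(p for p in ids if not labels[p]))
        order = np.concatenate([pos, neg])
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, pid in enumerate(order):
        folds[i % k].append(str(pid))
    return folds


def compute_metrics(labels, scores, threshold: float = 0.5):
    """(F1, AUROC).  F1 is 0 when there are no true positives at the
    threshold; AUROC requires both classes and credits ties 0.5."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUROC undefined for single-class labels")

    pred = s >= threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0

    ranks = rankdata(s)
    auroc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return f1, float(auroc)


def f1_score_only(labels, scores) -> float:
    return compute_metrics(labels, scores)[0]


def auroc_only(labels, scores) -> float:
    return compute_metrics(labels, scores)[1]


@dataclass(frozen=True)
class BootstrapCI:
    lower: float
    upper: float
    n_redrawn: int


def bootstrap_ci(labels, scores, metric, n_boot: int = 1000,
                 seed: int = 0) -> BootstrapCI:
    """Percentile 2.5/97.5 bounds over patient-level resamples.  Resamples
    with a single label class are redrawn; the redraw count is reported."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(y)
    values = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < y[idx].sum() < n:
                break
            redrawn += 1
        values[b] = metric(y[idx], s[idx])
    lower, upper = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(float(lower), float(upper), redrawn)


def nadeau_bengio_interval(fold_values, k: int) -> tuple[float, float]:
    """Corrected resampled t-interval over per-fold metrics.

    Uses the Nadeau-Bengio variance correction (1/k + 1/(k-1)) x fold
    variance, which accounts for the train-set overlap between folds that
    makes naive fold variances anticonservative.
    """
    values = np.asarray([v for v in fold_values if np.isfinite(v)])
    if len(values) < 2:
        return float("nan"), float("nan")
    from scipy.stats import t as t_dist

    hw = t_dist.ppf(0.975, len(values) - 1) * np.sqrt(
        (1.0 / k + 1.0 / (k - 1)) * values.var(ddof=1))
    return float(values.mean() - hw), float(values.mean() + hw)


def cv_interval(labels, scores, metric, fold_values, k: int,
                n_boot: int = 1000, seed: int = 0) -> "BootstrapCI":
    """95% CI for a cross-validated pooled metric.

    Union of the percentile patient bootstrap (evaluation-sampling
    variance) and the Nadeau-Bengio fold interval (model/fold variance);
    pooled cross-validated predictions are cross-correlated, so either
    component alone under-covers.
    """
    boot = bootstrap_ci(labels, scores, metric, n_boot, seed)
    nb_lo, nb_hi = nadeau_bengio_interval(fold_values, k)
    if np.isnan(nb_lo):
        return boot
    # both metrics live in [0, 1]; the fold interval is not range-aware
    return BootstrapCI(max(0.0, min(boot.lower, nb_lo)),
                       min(1.0, max(boot.upper, nb_hi)),
                       boot.n_redrawn)


@dataclass
class EvalResult:
    """Pooled cross-validated evaluation of one pipeline against one label."""

    name: str
    n_patients: int
    f1: float
    auroc: float
    f1_ci: BootstrapCI
    auroc_ci: BootstrapCI
    per_fold: list[dict]
    fold_map: dict[str, int]
    seed: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_patients": self.n_patients,
            "n_excluded": self.n_excluded,
            "f1": self.f1,
            "auroc": self.auroc,
            "f1_ci": [self.f1_ci.lower, self.f1_ci.upper],
            "auroc_ci": [self.auroc_ci.lower, self.auroc_ci.upper],
            "per_fold": self.per_fold,
            "seed": self.seed,
        }


def _audit_disjoint(train_ids, test_ids):
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise AssertionError(
            f"leakage: patients in both train and test: {sorted(overlap)[:5]}")


def cross_validate_structured(count_maps: dict[str, dict[str, int]],
                              labels: dict[str, bool],
                              folds: list[list[str]],
                              spec: ModelSpec,
                              selection: tuple[str, float] = ("chi2", 500),
                              mapping: dict[str, str] | None = None,
                              name: str = "structured",
                              n_boot: int = 1000,
                              boot_seed: int = 0) -> EvalResult:
    """Run the full structured pipeline fold by fold.

    Vocabulary and selection mask are fitted on each training fold only; the
    mask changes dimensionality, never values.
    """
    all_ids = [pid for fold in folds for pid in fold]
    pooled_scores = {}
    per_fold = []
    fold_map = {}
    for fold_idx, test_ids in enumerate(folds):
        train_ids = [pid for f, fold in enumerate(folds) if f != fold_idx
                     for pid in fold]
        _audit_disjoint(train_ids, test_ids)
        vocab = FeatureVocabulary.fit(
            [count_maps[pid] for pid in train_ids], mapping=mapping)
        x_train = vocab.transform([count_maps[pid] for pid in train_ids])
        y_train = np.array([labels[pid] for pid in train_ids], dtype=bool)
        mask = select_features(x_train, y_train, *selection)
        if not mask.any():
            raise ConfigurationError(
                "feature selection removed every feature")
        x_test = vocab.transform([count_maps[pid] for pid in test_ids])
        scores = fit_predict(spec, x_train[:, mask], y_train,
                             x_test[:, mask])
        y_test = np.array([labels[pid] for pid in test_ids], dtype=bool)
        fold_f1, fold_auroc = compute_metrics(y_test, scores)
        per_fold.append({"fold": fold_idx, "n": len(test_ids),
                         "f1": fold_f1, "auroc": fold_auroc})
        for pid, score in zip(test_ids, scores):
            pooled_scores[pid] = float(score)
            fold_map[pid] = fold_idx

    y = np.array([labels[pid] for pid in all_ids], dtype=bool)
    s = np.array([pooled_scores[pid] for pid in all_ids])
    f1, auroc = compute_metrics(y, s)
    k = len(folds)
    return EvalResult(
        name=name, n_patients=len(all_ids), f1=f1, auroc=auroc,
        f1_ci=cv_interval(y, s, f1_score_only,
                          [f["f1"] for f in per_fold], k, n_boot, boot_seed),
        auroc_ci=cv_interval(y, s, auroc_only,
                             [f["auroc"] for f in per_fold], k, n_boot,
                             boot_seed),
        per_fold=per_fold, fold_map=fold_map, seed=spec.seed)
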