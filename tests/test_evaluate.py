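import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from szrec.errors import SingleClassError
from szrec.evaluate import (
    ModelSpec,
    bootstrap_ci,
    compute_metrics,
    cv_interval,
    fit_predict,
    make_folds,
)

from _oracles import oracle_auroc, oracle_f1


# -- folds --------------------------------------------------------------------

def test_folds_partition_and_sizes():
    ids = [f"p{i}" for i in range(100)]
    folds = make_folds(ids, k=5, seed=1)
    assert sorted(len(f) for f in folds) == [20] * 5  # exact 80/20 split
    flat = [p for f in folds for p in f]
    assert sorted(flat) == sorted(ids)  # disjoint union = full id set


def test_folds_deterministic_and_seed_sensitive():
    ids = [f"p{i}" for i in range(57)]
    assert make_folds(ids, 5, seed=9) == make_folds(ids, 5, seed=9)
    assert make_folds(ids, 5, seed=9) != make_folds(ids, 5, seed=10)
    sizes = sorted(len(f) for f in make_folds(ids, 5, seed=9))
    assert max(sizes) - min(sizes) <= 1


def test_stratified_folds_balance_classes():
    ids = [f"p{i}" for i in range(100)]
    labels = {p: i < 30 for i, p in enumerate(ids)}
    folds = make_folds(ids, 5, seed=0, labels=labels)
    pos_counts = [sum(labels[p] for p in f) for f in folds]
    assert max(pos_counts) - min(pos_counts) <= 1


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError):
        make_folds(["a", "b"], k=3)


# -- metrics ------------------------------------------------------------------

def test_metric_closed_forms():
    y = [1, 1, 0, 0]
    assert compute_metrics(y, [1.0, 0.9, 0.1, 0.0]) == (1.0, 1.0)
    assert compute_metrics(y, [0.5] * 4)[1] == 0.5  # all ties
    assert compute_metrics([1, 0, 1, 0],
                           [0.9, 0.8, 0.4, 0.1])[1] == pytest.approx(0.75)


def test_single_class_labels_rejected():
    with pytest.raises(SingleClassError):
        compute_metrics([1, 1, 1], [0.5, 0.2, 0.9])


def test_auroc_matches_pairwise_oracle_1000_sets():
    """Rank-based AUROC equals O(n^2) pairwise enumeration, ties included;
    F1 matches direct precision/recall arithmetic."""
    rng = np.random.default_rng(5)
    for trial in range(1000):
        n = int(rng.integers(4, 30))
        y = rng.random(n) < rng.uniform(0.2, 0.8)
        if y.all() or not y.any():
            continue
        s = np.round(rng.random(n), 2)  # rounding produces plenty of ties
        f1, auroc = compute_metrics(y, s)
        assert auroc == pytest.approx(oracle_auroc(y, s), abs=1e-12)
        assert f1 == pytest.approx(oracle_f1(y, s), abs=1e-12)


def test_auroc_invariances():
    rng = np.random.default_rng(6)
    y = rng.random(60) < 0.5
    y[:2] = [True, False]
    s = rng.random(60)
    _, base = compute_metrics(y, s)
    # strictly monotone transform of scores leaves AUROC unchanged
    _, trans = compute_metrics(y, 1 / (1 + np.exp(-5 * s)))
    assert trans == pytest.approx(base)
    # label/score co-permutation leaves both metrics unchanged
    perm = rng.permutation(60)
    assert compute_metrics(y[perm], s[perm]) == \
        pytest.approx(compute_metrics(y, s))


def test_agreement_with_sklearn_on_random_data():
    rng = np.random.default_rng(7)
    y = rng.random(200) < 0.4
    y[:2] = [True, False]
    s = np.round(rng.random(200), 2)
    assert compute_metrics(y, s)[1] == pytest.approx(roc_auc_score(y, s))


# -- bootstrap ----------------------------------------------------------------

def test_bootstrap_deterministic_and_zero_width():
    y = np.array([1, 0, 1, 0, 1, 0] * 10, dtype=bool)
    s = np.full(60, 0.7)
    ci1 = bootstrap_ci(y, s, lambda a, b: compute_metrics(a, b)[1],
                       n_boot=200, seed=4)
    ci2 = bootstrap_ci(y, s, lambda a, b: compute_metrics(a, b)[1],
                       n_boot=200, seed=4)
    assert ci1 == ci2
    assert ci1.lower == ci1.upper == 0.5  # constant scores -> all ties


def test_bootstrap_covers_point_estimate():
    rng = np.random.default_rng(8)
    y = rng.random(400) < 0.5
    y[:2] = [True, False]
    s = np.clip(y + rng.normal(0, 0.8, 400), 0, 1)
    _, auroc = compute_metrics(y, s)
    ci = bootstrap_ci(y, s, lambda a, b: compute_metrics(a, b)[1],
                      n_boot=500, seed=0)
    assert ci.lower <= auroc <= ci.upper


def test_cv_interval_widens_with_fold_variance():
    rng = np.random.default_rng(3)
    y = rng.random(300) < 0.5
    y[:2] = [True, False]
    s = rng.random(300)
    auroc = lambda a, b: compute_metrics(a, b)[1]  # noqa: E731
    narrow = cv_interval(y, s, auroc, [0.50, 0.50, 0.50, 0.50, 0.50], k=5,
                         n_boot=200)
    wide = cv_interval(y, s, auroc, [0.30, 0.45, 0.55, 0.60, 0.70], k=5,
                       n_boot=200)
    assert wide.upper - wide.lower > narrow.upper - narrow.lower


# -- classifiers --------------------------------------------------------------

def test_separable_toy_data_perfect_auroc():
    x = sp.csr_matrix(np.array([[0.0], [0.1], [0.9], [1.0]] * 5))
    y = np.array([0, 0, 1, 1] * 5)
    scores = fit_predict(ModelSpec("elasticnet_logistic", seed=0), x, y, x)
    assert compute_metrics(y, scores)[1] == 1.0


def test_single_class_training_rejected():
    x = sp.csr_matrix(np.ones((4, 2)))
    with pytest.raises(SingleClassError):
        fit_predict(ModelSpec("elasticnet_logistic"), x, [1, 1, 1, 1], x)


def test_null_features_give_null_auroc():
    """Labels independent of features -> held-out AUROC inside the
    permutation-null 95% band around 0.5."""
    rng = np.random.default_rng(2)
    x = sp.csr_matrix(rng.random((400, 20)))
    y = rng.random(400) < 0.5
    scores = fit_predict(ModelSpec("elasticnet_logistic", seed=0),
                         x[:300], y[:300], x[300:])
    _, auroc = compute_metrics(y[300:], scores)
    null = []
    for _ in range(300):
        perm = rng.permutation(y[300:])
        if perm.all() or not perm.any():
            continue
        null.append(compute_metrics(perm, scores)[1])
    lo, hi = np.quantile(null, [0.025, 0.975])
    assert lo <= auroc <= hi


def test_class_balancing_robust_to_negative_duplication():
    """Duplicating every negative patient leaves the balanced elastic-net
    decision direction unchanged in sign on a 2-feature toy set."""
    from szrec.evaluate import build_estimator

    x = np.array([[1.0, 0.2], [0.9, 0.1], [0.8, 0.3],
                  [0.1, 0.9], [0.2, 0.8], [0.0, 1.0]])
    y = np.array([1, 1, 1, 0, 0, 0])
    m1 = build_estimator(ModelSpec("elasticnet_logistic", seed=0)).fit(x, y)
    x2 = np.vstack([x, x[y == 0]])
    y2 = np.concatenate([y, y[y == 0]])
    m2 = build_estimator(ModelSpec("elasticnet_logistic", seed=0)).fit(x2, y2)
    assert np.all(np.sign(m1.coef_) == np.sign(m2.coef_))


def test_gradient_boosted_family_learns_toy_signal():
    rng = np.random.default_rng(4)
    x = rng.random((300, 5))
    y = (x[:, 0] > 0.5).astype(int)
    scores = fit_predict(ModelSpec("gradient_boosted_trees", seed=0),
                         sp.csr_matrix(x[:200]), y[:200],
                         sp.csr_matrix(x[200:]))
    assert compute_metrics(y[200:], scores)[1] > 0.95
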