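"""Normalization, the five classifier families, grid search and CV splitting."""

import numpy as np
import pytest

from fallsense.classification import (ClassifierSpec, FAMILIES,
                                      apply_normalizer, evaluate,
                                      fit_normalizer, grid_search, kfold_split,
                                      predict, subjectwise_split, train)


@pytest.fixture
def clouds(rng):
    """Two well-separated Gaussian clouds, 40 points each."""
    X = np.vstack([rng.normal(0, 1, size=(40, 6)), rng.normal(8, 1, size=(40, 6))])
    y = np.repeat(["a", "b"], 40)
    return X, y


def test_normalizer_centers_and_scales_training_rows(rng):
    X = rng.normal(3, 5, size=(50, 4))
    norm = fit_normalizer(X)
    Z = apply_normalizer(norm, X)
    assert np.allclose(Z.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(Z.std(axis=0), 1, atol=1e-9)


def test_normalizer_constant_column_maps_to_zero(rng):
    X = rng.normal(size=(30, 3))
    X[:, 1] = 7.0
    norm = fit_normalizer(X)
    assert norm.scale[1] == 1.0
    assert np.all(apply_normalizer(norm, X)[:, 1] == 0.0)


def test_normalizer_heldout_rows_not_exactly_centered(rng):
    X = rng.normal(size=(100, 5))
    norm = fit_normalizer(X[:60])
    held = apply_normalizer(norm, X[60:])
    assert not np.allclose(held.mean(axis=0), 0, atol=1e-6)
    assert np.all(np.abs(held.mean(axis=0)) < 0.5)


def test_normalizer_needs_two_rows():
    with pytest.raises(ValueError):
        fit_normalizer(np.ones((1, 3)))


@pytest.mark.parametrize("family", FAMILIES)
def test_every_family_separates_gaussian_clouds(family, clouds):
    X, y = clouds
    model = train(ClassifierSpec(family), X, y)
    acc = np.mean(predict(model, X) == y)
    assert acc >= 0.99


def test_train_rejects_single_class_and_nan(clouds):
    X, y = clouds
    with pytest.raises(ValueError, match="class"):
        train(ClassifierSpec("svm-rbf"), X, np.repeat("a", len(y)))
    X_bad = X.copy()
    X_bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        train(ClassifierSpec("svm-rbf"), X_bad, y)


def test_knn_majority_vote_on_tied_distances():
    X = np.array([[0.0, 1.0], [0.0, -1.0], [2.0, 1.0], [0.0, 3.0]])
    y = np.array(["a", "a", "b", "a"])
    model = train(ClassifierSpec("knn", k=3), X, y)
    # query equidistant from all of (0,1), (2,1), (0,3): 2 a's vs 1 b
    assert predict(model, np.array([[1.0, 2.0]]))[0] == "a"


def test_svm_grid_evaluates_121_combinations(clouds):
    X, y = clouds
    trace = []
    best = grid_search("svm-rbf", X, y, folds=5, seed=0, trace=trace)
    assert len(trace) == 121
    best_acc = next(a for p, a in trace
                    if p == {"C": best.C, "gamma": best.gamma})
    assert best_acc == max(a for _, a in trace)


def test_grid_ties_break_to_first_in_ascending_order(clouds):
    X, y = clouds  # trivially separable: many grid points tie at 1.0
    trace = []
    best = grid_search("svm-rbf", X, y, folds=5, seed=0, trace=trace)
    top = max(a for _, a in trace)
    first = next(p for p, a in trace if a == top)
    assert {"C": best.C, "gamma": best.gamma} == first


def test_grid_search_rejects_hyperparameterless_family(clouds):
    X, y = clouds
    with pytest.raises(ValueError, match="train"):
        grid_search("naive-bayes", X, y)


def test_kfold_is_a_stratified_partition():
    y = np.repeat(["a", "b", "c", "d"], 30)  # 120 rows
    folds = kfold_split(y, k=10, seed=1)
    assert len(folds) == 10
    all_test = np.concatenate([te for _, te in folds])
    assert sorted(all_test) == list(range(120))
    for _, te in folds:
        _, counts = np.unique(y[te], return_counts=True)
        assert np.all(counts == 3)  # 12 per fold, 3 per class


def test_subjectwise_split_is_leave_one_subject_out():
    subjects = np.repeat([f"S{i}" for i in range(9)], 4)
    folds = subjectwise_split(subjects)
    assert len(folds) == 9
    for tr, te in folds:
        assert len(set(subjects[te])) == 1
        assert subjects[te][0] not in set(subjects[tr])
    with pytest.raises(ValueError):
        subjectwise_split(np.repeat("S1", 5))


def test_evaluate_perfectly_separable_data(clouds):
    X, y = clouds
    res = evaluate(ClassifierSpec("knn"), X, y, scheme="kfold-10", seed=0)
    assert res.accuracy == 1.0
    assert np.all(res.confusion_matrix == np.diag([40, 40]))


def test_confusion_matrix_total_is_row_count(rng):
    X = rng.normal(size=(60, 4))
    y = rng.choice(["a", "b", "c"], size=60)
    res = evaluate(ClassifierSpec("decision-tree"), X, y, scheme="kfold-10", seed=2)
    assert res.confusion_matrix.sum() == 60


def test_no_leakage_training_stats_ignore_test_rows(rng):
    X = rng.normal(size=(80, 6))
    y = np.tile(["a", "b"], 40)
    for tr, te in kfold_split(y, k=10, seed=3):
        norm = fit_normalizer(X[tr])
        X_corrupt = X.copy()
        X_corrupt[te] *= 1e3
        norm2 = fit_normalizer(X_corrupt[tr])
        assert np.array_equal(norm.mean, norm2.mean)
        assert np.array_equal(norm.scale, norm2.scale)


def test_smlr_sparsity_never_grows_with_lambda(rng):
    X = np.vstack([rng.normal(0, 1, size=(60, 20)), rng.normal(1.5, 1, size=(60, 20))])
    X[:, 10:] = rng.normal(size=(120, 10))  # irrelevant features
    y = np.repeat(["a", "b"], 60)
    nonzeros = []
    for lam in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
        model = train(ClassifierSpec("smlr", lam=lam), X, y)
        nonzeros.append(int(np.sum(np.abs(model.estimator.coef_) > 1e-6)))
    assert all(a >= b for a, b in zip(nonzeros, nonzeros[1:]))
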