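"""Cross-validation, ROC averaging and repeated evaluation."""

import numpy as np
import pandas as pd
import pytest

from radpipe import (
    ModelSpec,
    TableSpec,
    average_roc,
    cross_validate,
    evaluate_test_set,
    generate_feature_table,
    make_folds,
    repeat_evaluation,
    split_train_test,
)
from radpipe.modeling import build_classifier


def imbalanced_table(seed=0, effect=1.5, p=5):
    spec = TableSpec(
        n_per_class=(64, 28), n_features=p, batch_sizes=(92,),
        effects=((0, effect),), seed=seed,
    )
    return generate_feature_table(spec)[0]


def test_split_fraction_zero_is_cv_only_mode():
    table = imbalanced_table()
    train, test = split_train_test(table, 0.0)
    assert len(train) == len(table)
    assert len(test) == 0


def test_split_quarter_stratified():
    table = imbalanced_table()
    train, test = split_train_test(table, 0.25, stratify=True, seed=1)
    assert len(train) + len(test) == 92
    assert (test["label"] == 1).sum() == 7
    assert (test["label"] == 0).sum() == 16
    # determinism
    train2, test2 = split_train_test(table, 0.25, stratify=True, seed=1)
    assert list(test["patient_id"]) == list(test2["patient_id"])


def test_make_folds_partition_and_stratification():
    table = imbalanced_table()
    y = table["label"].to_numpy()
    folds = make_folds(y, 10, stratified=True, seed=0)
    assert sum(len(f) for f in folds) == 92
    all_idx = np.sort(np.concatenate(folds))
    np.testing.assert_array_equal(all_idx, np.arange(92))
    for fold in folds:
        assert 2 <= (y[fold] == 1).sum() <= 3
    # leave-one-out boundary
    loo = make_folds(np.array([0, 1] * 5), 10, stratified=False, seed=0)
    assert all(len(f) == 1 for f in loo)
    with pytest.raises(ValueError, match="k must lie"):
        make_folds(y, 93)


@pytest.mark.parametrize("kind", ["lda", "knn", "svm"])
def test_separable_classes_classified_perfectly(kind):
    rng = np.random.default_rng(0)
    n = 100
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(0, 1, size=n) + 10.0 * y  # 10 sigma separation
    table = pd.DataFrame(
        {"patient_id": [f"p{i}" for i in range(n)], "label": y, "f": x}
    )
    folds = make_folds(y, 5, stratified=True, seed=0)
    report = cross_validate(table, ModelSpec(kind), folds)
    assert all(f["auc"] == 1.0 for f in report.folds)
    assert report.mean_metrics["accuracy"] == 1.0
    assert np.sum(report.total_confusion) == n


def test_total_confusion_sums_to_n():
    table = imbalanced_table()
    folds = make_folds(table["label"].to_numpy(), 10, True, 0)
    report = cross_validate(table, ModelSpec("lda"), folds)
    assert int(np.sum(report.total_confusion)) == 92


def test_metrics_invariant_to_feature_column_order():
    table = imbalanced_table(p=4)
    feats = [c for c in table.columns if c.startswith("feat_")]
    reordered = table[["patient_id", "label", "batch"] + feats[::-1]]
    folds = make_folds(table["label"].to_numpy(), 5, True, 0)
    a = cross_validate(table, ModelSpec("lda"), folds)
    b = cross_validate(reordered, ModelSpec("lda"), folds)
    assert a.mean_metrics == pytest.approx(b.mean_metrics)


def test_average_roc_idempotent_and_boundary():
    fpr = np.array([0.0, 0.2, 0.6, 1.0])
    tpr = np.array([0.0, 0.5, 0.8, 1.0])
    grid, mean_tpr, auc1 = average_roc([(fpr, tpr)])
    np.testing.assert_allclose(mean_tpr, np.interp(grid, fpr, tpr))
    grid2, mean2, auc2 = average_roc([(fpr, tpr), (fpr, tpr)])
    np.testing.assert_allclose(mean_tpr, mean2)
    assert auc1 == pytest.approx(auc2)
    # two perfect curves -> averaged AUC 1
    perfect = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]))
    assert average_roc([perfect, perfect])[2] == pytest.approx(1.0, abs=1e-2)


def test_average_roc_mixed_curves():
    """Diagonal (AUC 0.5) + perfect (AUC 1.0): the vertical average is
    (f+1)/2 on the grid, whose trapezoid area is 0.75."""
    diagonal = (np.array([0.0, 1.0]), np.array([0.0, 1.0]))
    perfect = (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]))
    _, _, auc = average_roc([diagonal, perfect])
    assert auc == pytest.approx(0.75, abs=0.01)
    with pytest.raises(ValueError, match="at least one"):
        average_roc([])


def test_repeat_evaluation_deterministic_and_summarised():
    table = imbalanced_table()
    a = repeat_evaluation(table, ModelSpec("lda"), k=5, n_repeats=3, base_seed=9)
    b = repeat_evaluation(table, ModelSpec("lda"), k=5, n_repeats=3, base_seed=9)
    assert a.to_dict() == b.to_dict()
    assert len(a.repeats) == 3
    assert a.seeds == [9, 10, 11]
    for name in ("auc", "accuracy", "sensitivity", "specificity"):
        entry = a.summary[name]
        assert "ci95" in entry
        lo, hi = entry["ci95"]
        assert lo <= entry["mean"] <= hi
    single = repeat_evaluation(table, ModelSpec("lda"), k=5, n_repeats=1, base_seed=0)
    assert "ci95" not in single.summary["auc"]


def test_imbalance_gives_low_sensitivity_high_specificity():
    """With 28 positives vs 64 negatives and a weak signal, the 0.5
    threshold favours the majority class."""
    table = imbalanced_table(effect=0.8, seed=5)
    rep = repeat_evaluation(table, ModelSpec("lda"), k=10, n_repeats=5, base_seed=1)
    assert rep.summary["sensitivity"]["mean"] < rep.summary["specificity"]["mean"]


def test_evaluate_test_set_cases():
    table = imbalanced_table()
    feats = [c for c in table.columns if c.startswith("feat_")]
    clf = build_classifier(ModelSpec("lda"))
    clf.fit(table[feats].to_numpy(), table["label"].to_numpy())
    # memorization: training data re-used as test set, separable enough
    metrics = evaluate_test_set(clf, table, features=feats)
    assert metrics["accuracy"] >= 0.5
    assert np.asarray(metrics["confusion"]).sum() == len(table)
    # empty test set -> no-op
    assert evaluate_test_set(clf, table.iloc[0:0], features=feats) is None
    # single-class test set: accuracy defined, AUC absent
    single = table[table["label"] == 1]
    metrics = evaluate_test_set(clf, single, features=feats)
    assert np.isnan(metrics["auc"])
    assert 0.0 <= metrics["accuracy"] <= 1.0


def test_null_labels_give_chance_auc():
    rng = np.random.default_rng(3)
    spec = TableSpec(
        n_per_class=(100, 100), n_features=5, batch_sizes=(200,), seed=3
    )
    table, _ = generate_feature_table(spec)
    table["label"] = rng.permutation(table["label"].to_numpy())
    rep = repeat_evaluation(table, ModelSpec("lda"), k=5, n_repeats=3, base_seed=0)
    assert 0.35 <= rep.summary["auc"]["mean"] <= 0.65


def test_degenerate_training_fold_rejected():
    table = imbalanced_table().iloc[:10]
    folds = [np.arange(5), np.arange(5, 10)]
    y = table["label"].to_numpy().copy()
    y[5:] = 1
    table = table.assign(label=y)
    bad_folds = [np.nonzero(y == 0)[0]]  # training remainder is all class 1
    with pytest.raises(ValueError, match="single class"):
        cross_validate(table, ModelSpec("lda"), bad_folds)
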