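"""Cross-validated classification, per-class metrics and importances."""
import numpy as np
import pandas as pd
import pytest

from octfib.classify import (
    MODEL_FAMILIES,
    CvReport,
    ModelSpec,
    build_estimator,
    compare_models,
    feature_importances,
    kfold_train_eval,
    per_class_metrics,
)
from octfib.dataset import FEATURE_COLUMNS, LabeledDataset


def blob_dataset(rng, n_per_class=20, sep=6.0):
    """Three Gaussian blobs in 25-d, separated along the first two features."""
    centers = {"advanced": (0, 0), "mild": (sep, 0), "normal": (0, sep)}
    rows, labels = [], []
    for lab, (cx, cy) in centers.items():
        X = rng.normal(size=(n_per_class, len(FEATURE_COLUMNS)))
        X[:, 0] += cx
        X[:, 1] += cy
        rows.append(X)
        labels += [lab] * n_per_class
    return LabeledDataset(
        features=pd.DataFrame(np.vstack(rows), columns=list(FEATURE_COLUMNS)),
        labels=np.array(labels, object),
    )


def test_separable_blobs_high_accuracy(rng):
    ds = blob_dataset(rng, n_per_class=20)
    report = kfold_train_eval(ds, ModelSpec("gradient_boosting"), k=10, seed=0)
    assert report.accuracy >= 0.95


def test_label_permutation_near_chance(rng):
    ds = blob_dataset(rng, n_per_class=100)
    perm = rng.permutation(len(ds))
    shuffled = LabeledDataset(features=ds.features, labels=ds.labels[perm])
    report = kfold_train_eval(shuffled, ModelSpec("gradient_boosting"), k=10, seed=0)
    n = len(ds)
    half_width = 2.576 * np.sqrt((1 / 3) * (2 / 3) / n)
    assert abs(report.accuracy - 1 / 3) <= half_width + 0.05


def test_fixed_seed_reproducibility(rng):
    ds = blob_dataset(rng, n_per_class=15, sep=2.0)
    r1 = kfold_train_eval(ds, ModelSpec(), k=5, seed=3)
    r2 = kfold_train_eval(ds, ModelSpec(), k=5, seed=3)
    assert np.array_equal(r1.confusion, r2.confusion)
    assert r1.accuracy == r2.accuracy
    assert r1.importances == r2.importances


def test_k_larger_than_class_rejected(rng):
    ds = blob_dataset(rng, n_per_class=5)
    with pytest.raises(ValueError, match="k"):
        kfold_train_eval(ds, k=10, seed=0)


def test_confusion_row_sums_invariant_across_models(rng):
    ds = blob_dataset(rng, n_per_class=12, sep=2.0)
    reports = [
        kfold_train_eval(ds, ModelSpec(f), k=4, seed=9)
        for f in ("gradient_boosting", "decision_tree")
    ]
    sums = [r.confusion.sum(axis=1).tolist() for r in reports]
    assert sums[0] == sums[1] == [12, 12, 12]


class TestPerClassMetrics:
    def test_diagonal_matrix_perfect(self):
        m = per_class_metrics(np.diag([5, 7, 9]))
        for cls in m:
            for key in ("precision", "recall", "specificity", "f1"):
                assert m[cls][key] == 1.0

    def test_never_predicted_class(self):
        confusion = np.array([[5, 0, 0], [5, 0, 0], [0, 0, 5]])
        m = per_class_metrics(confusion)
        mild = m["mild"]
        assert mild["precision"] == 0.0 and "precision_undefined" in mild["flags"]
        assert mild["recall"] == 0.0
        assert mild["specificity"] == 1.0

    def test_hand_computed_oracle(self):
        confusion = np.array([[8, 1, 1], [2, 6, 2], [0, 1, 9]])
        m = per_class_metrics(confusion)
        # advanced (one-vs-rest): TP=8 FP=2 FN=2 TN=18
        assert m["advanced"]["precision"] == pytest.approx(8 / 10)
        assert m["advanced"]["recall"] == pytest.approx(8 / 10)
        assert m["advanced"]["specificity"] == pytest.approx(18 / 20)
        assert m["advanced"]["f1"] == pytest.approx(2 * 0.8 * 0.8 / 1.6)
        # mild: TP=6 FP=2 FN=4 TN=18
        assert m["mild"]["precision"] == pytest.approx(6 / 8)
        assert m["mild"]["recall"] == pytest.approx(6 / 10)
        assert m["mild"]["specificity"] == pytest.approx(18 / 20)
        assert m["mild"]["f1"] == pytest.approx(2 * (6 / 8) * (6 / 10) / ((6 / 8) + (6 / 10)))
        # normal: TP=9 FP=3 FN=1 TN=17
        assert m["normal"]["precision"] == pytest.approx(9 / 12)
        assert m["normal"]["recall"] == pytest.approx(9 / 10)
        assert m["normal"]["specificity"] == pytest.approx(17 / 20)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            per_class_metrics(np.array([[1, -1], [0, 2]]))


class TestCompareModels:
    def test_ranking_consistency(self, rng):
        ds = blob_dataset(rng, n_per_class=12, sep=4.0)
        rows = compare_models(ds, [ModelSpec("gradient_boosting"), ModelSpec("decision_tree")], k=4, seed=1)
        corrects = [r["correct"] for r in rows]
        assert corrects == sorted(corrects, reverse=True)
        for r in rows:
            assert r["correct"] == int(np.trace(r["report"].confusion))

    def test_identical_candidates_tie_break_by_order(self, rng):
        ds = blob_dataset(rng, n_per_class=12, sep=4.0)
        a, b = ModelSpec("gradient_boosting"), ModelSpec("gradient_boosting")
        rows = compare_models(ds, [a, b], k=4, seed=1)
        assert rows[0]["spec"] is a

    def test_single_candidate_rejected(self, rng):
        ds = blob_dataset(rng, n_per_class=12)
        with pytest.raises(ValueError):
            compare_models(ds, [ModelSpec()], k=4, seed=1)


class TestImportances:
    def test_single_informative_feature_dominates(self, rng):
        X = rng.normal(size=(120, len(FEATURE_COLUMNS)))
        labels = np.where(X[:, 5] > 0, "advanced", "normal").astype(object)
        est = build_estimator(ModelSpec("gradient_boosting"), seed=0)
        est.fit(X, labels)
        imp = feature_importances(est)
        top_feature, top_value = next(iter(imp.items()))
        assert top_feature == FEATURE_COLUMNS[5]
        assert top_value > 0.5

    def test_noise_features_diffuse(self, rng):
        X = rng.normal(size=(150, len(FEATURE_COLUMNS)))
        labels = rng.choice(["advanced", "mild", "normal"], size=150).astype(object)
        est = build_estimator(ModelSpec("gradient_boosting"), seed=0)
        est.fit(X, labels)
        imp = feature_importances(est)
        assert all(v < 0.5 for v in imp.values())

    def test_filter_contract(self, rng):
        X = rng.normal(size=(90, len(FEATURE_COLUMNS)))
        labels = np.where(X[:, 0] + X[:, 1] > 0, "mild", "normal").astype(object)
        est = build_estimator(ModelSpec("gradient_boosting"), seed=0)
        est.fit(X, labels)
        imp = feature_importances(est)
        assert all(v >= 0.01 for v in imp.values())
        assert list(imp.values()) == sorted(imp.values(), reverse=True)

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError):
            feature_importances(build_estimator(ModelSpec("logistic_regression")))

    def test_logistic_importances_normalized(self, rng):
        X = rng.normal(size=(90, len(FEATURE_COLUMNS)))
        labels = np.where(X[:, 2] > 0, "mild", "normal").astype(object)
        est = build_estimator(ModelSpec("logistic_regression"), seed=0)
        est.fit(X, labels)
        imp = feature_importances(est)
        assert next(iter(imp)) == FEATURE_COLUMNS[2]
        assert sum(imp.values()) <= 1.0 + 1e-9


def test_all_model_families_buildable():
    for fam in MODEL_FAMILIES:
        est = build_estimator(ModelSpec(fam), seed=0)
        assert hasattr(est, "fit")


def test_smote_mode_does_not_change_test_rows(rng):
    # identical folds: the pooled confusion row sums (true-class counts of the
    # test rows) must match between off and inside_folds
    ds = blob_dataset(rng, n_per_class=10, sep=2.0)
    r_off = kfold_train_eval(ds, k=5, seed=2, smote_mode="off")
    r_in = kfold_train_eval(ds, k=5, seed=2, smote_mode="inside_folds")
    assert r_off.confusion.sum(axis=1).tolist() == r_in.confusion.sum(axis=1).tolist()
    assert r_off.total == r_in.total == len(ds)
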