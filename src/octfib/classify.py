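"""Three-class severity classification with stratified k-fold validation.

Five candidate model families are supported — gradient boosting, logistic
regression, a single decision tree, bagged decision trees and AdaBoost — with
gradient boosting as the reference model. Validation pools out-of-fold
predictions from a stratified k-fold into one confusion matrix from which
accuracy and one-vs-rest per-class precision, recall, specificity and F1 are
computed. SMOTE can be fitted inside each training fold (default; no synthetic
sample ever reaches a test fold), applied up front to the whole table
(matching how the balanced 60-row table was built), or disabled.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .dataset import FEATURE_COLUMNS, LabeledDataset, smote_balance
from .types import CLASSES

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "CvReport",
    "build_estimator",
    "kfold_train_eval",
    "per_class_metrics",
    "compare_models",
    "feature_importances",
]

#: The five candidate families, in canonical order.
MODEL_FAMILIES: tuple[str, ...] = (
    "gradient_boosting",
    "logistic_regression",
    "decision_tree",
    "bagged_decision_tree",
    "ada_boost",
)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate classifier: family name plus hyperparameter overrides."""

    family: str = "gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}, got {self.family!r}")


@dataclass
class CvReport:
    """Pooled cross-validation result.

    ``confusion`` rows are true classes, columns predicted, both in
    :data:`octfib.types.CLASSES` order.
    """

    confusion: np.ndarray
    accuracy: float
    per_class: dict[str, dict[str, float]]
    importances: dict[str, float]
    fold_seed: int
    correct: int = 0
    total: int = 0


def build_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the sklearn estimator for a model spec."""
    hp = dict(spec.hyperparameters)
    hp.setdefault("random_state", seed)
    if spec.family == "gradient_boosting":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("learning_rate", 0.1)
        hp.setdefault("max_depth", 3)
        return GradientBoostingClassifier(**hp)
    if spec.family == "logistic_regression":
        hp.setdefault("max_iter", 2000)
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(**hp))]
        )
    if spec.family == "decision_tree":
        return DecisionTreeClassifier(**hp)
    if spec.family == "bagged_decision_tree":
        hp.setdefault("n_estimators", 50)
        return BaggingClassifier(estimator=DecisionTreeClassifier(), **hp)
    if spec.family == "ada_boost":
        hp.setdefault("n_estimators", 100)
        return AdaBoostClassifier(**hp)
    raise AssertionError(spec.family)


def kfold_train_eval(
    ds: LabeledDataset,
    model: ModelSpec | None = None,
    k: int = 10,
    seed: int = 0,
    smote_mode: str = "inside_folds",
) -> CvReport:
    """Stratified k-fold validation with pooled out-of-fold predictions.

    ``smote_mode``:

    * ``inside_folds`` — SMOTE refitted on each training fold only (test folds
      never see synthetic rows created from their own data);
    * ``before_cv`` — the caller's dataset is balanced once up front (this
      reproduces building the balanced table before validation);
    * ``off`` — no balancing.

    Deterministic for a fixed ``seed``.
    """
    if model is None:
        model = ModelSpec()
    if smote_mode not in ("inside_folds", "before_cv", "off"):
        raise ValueError("smote_mode must be inside_folds, before_cv or off")
    work = smote_balance(ds, seed=seed) if smote_mode == "before_cv" else ds
    counts = work.class_counts()
    smallest = min(counts.values())
    if k > smallest:
        raise ValueError(
            f"k={k} exceeds the smallest class count {smallest}; use k <= {smallest}"
        )

    X = work.X
    y = work.labels.astype(str)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        if smote_mode == "inside_folds":
            fold_ds = LabeledDataset(
                features=work.features.iloc[train_idx].reset_index(drop=True),
                labels=work.labels[train_idx],
            )
            fold_ds = smote_balance(fold_ds, seed=seed)
            X_tr, y_tr = fold_ds.X, fold_ds.labels.astype(str)
        else:
            X_tr, y_tr = X[train_idx], y[train_idx]
        est = build_estimator(model, seed=seed)
        est.fit(X_tr, y_tr)
        y_pred[test_idx] = est.predict(X[test_idx])

    classes = [c for c in CLASSES if c in set(y)]
    lut = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for yt, yp in zip(y, y_pred):
        confusion[lut[yt], lut.get(yp, -1)] += 1
    correct = int(np.trace(confusion))

    final = build_estimator(model, seed=seed)
    fit_ds = smote_balance(work, seed=seed) if smote_mode == "inside_folds" else work
    final.fit(fit_ds.X, fit_ds.labels.astype(str))
    try:
        importances = feature_importances(final)
    except ValueError:
        importances = {}

    return CvReport(
        confusion=confusion,
        accuracy=correct / len(y),
        per_class=per_class_metrics(confusion, classes),
        importances=importances,
        fold_seed=seed,
        correct=correct,
        total=len(y),
    )


def per_class_metrics(
    confusion: np.ndarray, classes: list[str] | None = None
) -> dict[str, dict[str, float]]:
    """One-vs-rest precision, recall, specificity and F1 per class.

    Zero-denominator metrics are reported as 0.0 and named in the class's
    ``flags`` entry.
    """
    confusion = np.asarray(confusion)
    if (confusion < 0).any():
        raise ValueError("confusion matrix entries must be nonnegative")
    if classes is None:
        classes = list(CLASSES)[: confusion.shape[0]]
    total = confusion.sum()
    out: dict[str, dict[str, float]] = {}
    for i, cls in enumerate(classes):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        tn = total - tp - fp - fn
        flags = []

        def ratio(num, den, name):
            if den == 0:
                flags.append(name)
                return 0.0
            return float(num / den)

        precision = ratio(tp, tp + fp, "precision_undefined")
        recall = ratio(tp, tp + fn, "recall_undefined")
        specificity = ratio(tn, tn + fp, "specificity_undefined")
        f1 = ratio(2 * precision * recall, precision + recall, "f1_undefined")
        out[cls] = {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
            "flags": flags,
        }
    return out


def _macro_f1(report: CvReport) -> float:
    return float(np.mean([m["f1"] for m in report.per_class.values()]))


def compare_models(
    ds: LabeledDataset,
    candidates: list[ModelSpec] | None = None,
    k: int = 10,
    seed: int = 0,
    smote_mode: str = "inside_folds",
) -> list[dict]:
    """Rank candidate models by pooled correct out-of-fold predictions.

    Every candidate is evaluated with identical folds (same seed). Ties break
    by macro-F1, then by candidate order. Returns a list of dicts with keys
    ``spec``, ``report``, ``correct`` sorted best first.
    """
    if candidates is None:
        candidates = [ModelSpec(f) for f in MODEL_FAMILIES]
    if len(candidates) < 2:
        raise ValueError("need at least two candidates to compare")
    rows = []
    for pos, spec in enumerate(candidates):
        report = kfold_train_eval(ds, spec, k=k, seed=seed, smote_mode=smote_mode)
        rows.append({"spec": spec, "report": report, "correct": report.correct, "_pos": pos})
    rows.sort(key=lambda r: (-r["correct"], -_macro_f1(r["report"]), r["_pos"]))
    for r in rows:
        del r["_pos"]
    return rows


def feature_importances(model, min_importance: float = 0.01) -> dict[str, float]:
    """Importances of a trained model, filtered to >= ``min_importance``.

    Tree ensembles use impurity-based importances; logistic regression uses
    mean absolute standardized coefficients normalized to sum to 1. Returned
    in descending order.
    """
    if isinstance(model, Pipeline):
        clf = model.named_steps.get("clf", None)
        if isinstance(clf, LogisticRegression):
            if not hasattr(clf, "coef_"):
                raise ValueError("model is not trained")
            raw = np.abs(clf.coef_).mean(axis=0)
            raw = raw / raw.sum() if raw.sum() > 0 else raw
        else:
            raise ValueError("unsupported pipeline")
    elif hasattr(model, "feature_importances_"):
        raw = np.asarray(model.feature_importances_)
    elif hasattr(model, "estimators_") or hasattr(model, "coef_"):
        raise ValueError("importances undefined for this model family")
    else:
        raise ValueError("model is not trained")
    pairs = [
        (FEATURE_COLUMNS[i], float(v))
        for i, v in enumerate(raw)
        if v >= min_importance and i < len(FEATURE_COLUMNS)
    ]
    pairs.sort(key=lambda p: -p[1])
    return dict(pairs)
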