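"""Participant-independent nested cross-validated SVM classification.

Binary discrimination between a patient group and its comparison group from
per-retelling feature vectors, with the evaluation discipline used for
speech-derived biomarkers: an outer stratified five-fold split over
*participants* (each participant's data is either training or testing in a
given iteration, never both), an inner four-fold randomized search over the
RBF-SVM hyperparameters (C, gamma) on training participants only, and
feature extractors that are refitted inside every outer training fold so no
held-out information leaks into the semantic space.

Decision scores from the held-out folds are pooled into a single ROC/AUC,
and confusion matrices are aggregated across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import loguniform
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: randomized-search ranges (log-uniform), config-exposed
C_RANGE = (1e-2, 1e3)
GAMMA_RANGE = (1e-4, 1e1)


@dataclass(frozen=True)
class HyperParams:
    C: float
    gamma: float


@dataclass
class CVPlan:
    """Outer 5-fold stratified participant split plus the inner fold count."""

    outer: list[tuple[tuple[str, ...], tuple[str, ...]]]  # (train_ids, test_ids)
    n_inner: int
    seed: int


@dataclass
class FoldResult:
    params: HyperParams
    inner_accuracy: float
    test_ids: tuple[str, ...]
    scores: np.ndarray
    predictions: np.ndarray
    truth: np.ndarray


@dataclass
class ClassificationReport:
    """Pooled nested-CV outcome. Rates are percentages; AUC is in [0, 1].

    ``confusion`` is [[TN, FP], [FN, TP]] with the patient class positive.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    auc: float
    confusion: np.ndarray
    roc: np.ndarray  # (n_points, 2): fpr, tpr
    per_fold: list[FoldResult] = field(default_factory=list)


def make_cv_plan(
    participant_ids: Sequence[str],
    labels: dict[str, int] | Sequence[int],
    seed: int,
    n_outer: int = 5,
    n_inner: int = 4,
) -> CVPlan:
    """Stratified-by-label partition of participants into outer folds."""
    ids = list(participant_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("participant_ids must be unique")
    if isinstance(labels, dict):
        y = np.asarray([labels[p] for p in ids])
    else:
        y = np.asarray(list(labels))
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if counts.min() < n_outer:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify "
            f"into {n_outer} folds"
        )
    skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
    ids_arr = np.asarray(ids)
    outer = [
        (tuple(ids_arr[tr]), tuple(ids_arr[te]))
        for tr, te in skf.split(ids_arr, y)
    ]
    return CVPlan(outer=outer, n_inner=n_inner, seed=seed)


def sample_hyperparams(
    rng: np.random.Generator,
    n: int,
    c_range: tuple[float, float] = C_RANGE,
    gamma_range: tuple[float, float] = GAMMA_RANGE,
) -> list[HyperParams]:
    """n log-uniform draws of (C, gamma)."""
    cs = loguniform.rvs(*c_range, size=n, random_state=rng)
    gs = loguniform.rvs(*gamma_range, size=n, random_state=rng)
    return [HyperParams(float(c), float(g)) for c, g in zip(cs, gs)]


def _make_svm(params: HyperParams):
    # feature columns are standardized with training-fold statistics; an
    # RBF kernel on raw, arbitrarily scaled features is not meaningful
    return make_pipeline(
        StandardScaler(), SVC(kernel="rbf", C=params.C, gamma=params.gamma)
    )


FeatureFn = Callable[
    [Sequence[str], Sequence[str]], tuple[np.ndarray, np.ndarray]
]


def nested_cv(
    feature_fn: FeatureFn,
    labels: dict[str, int],
    plan: CVPlan,
    search_budget: int = 50,
    seed: int | None = None,
) -> ClassificationReport:
    """Run the nested cross-validation.

    ``feature_fn(train_ids, test_ids) -> (X_train, X_test)`` must fit any
    trainable parts (vocabulary, LSA space, reference verbs, importance) on
    the training participants only — e.g. a closure over
    :func:`prsf.metric.fit_transform_fold`. ``labels`` maps participant to
    0 (comparison class) / 1 (patient class, positive).
    """
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    all_scores, all_truth, all_pred = [], [], []
    per_fold: list[FoldResult] = []
    for fold_i, (train_ids, test_ids) in enumerate(plan.outer):
        X_tr, X_te = feature_fn(train_ids, test_ids)
        y_tr = np.asarray([labels[p] for p in train_ids])
        y_te = np.asarray([labels[p] for p in test_ids])
        if np.ptp(X_tr) == 0:
            logger.warning("fold %d: constant feature matrix; expect chance", fold_i)
        candidates = sample_hyperparams(rng, search_budget)
        inner = StratifiedKFold(
            n_splits=plan.n_inner, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        splits = list(inner.split(X_tr, y_tr))
        best, best_acc = None, -1.0
        for params in candidates:
            accs = []
            for itr, ival in splits:
                clf = _make_svm(params)
                clf.fit(X_tr[itr], y_tr[itr])
                accs.append(clf.score(X_tr[ival], y_tr[ival]))
            acc = float(np.mean(accs))
            if acc > best_acc:  # ties keep the first-sampled candidate
                best, best_acc = params, acc
        clf = _make_svm(best)
        clf.fit(X_tr, y_tr)
        scores = clf.decision_function(X_te)
        pred = clf.predict(X_te)
        per_fold.append(
            FoldResult(best, best_acc, tuple(test_ids), scores, pred, y_te)
        )
        all_scores.append(scores)
        all_truth.append(y_te)
        all_pred.append(pred)
    scores = np.concatenate(all_scores)
    truth = np.concatenate(all_truth)
    pred = np.concatenate(all_pred)
    confusion = _confusion(truth, pred)
    report = compute_metrics(confusion, scores, truth)
    report.per_fold = per_fold
    return report


def _confusion(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    tn = int(np.sum((truth == 0) & (pred == 0)))
    fp = int(np.sum((truth == 0) & (pred == 1)))
    fn = int(np.sum((truth == 1) & (pred == 0)))
    tp = int(np.sum((truth == 1) & (pred == 1)))
    return np.array([[tn, fp], [fn, tp]])


def compute_metrics(
    confusion: np.ndarray, scores: np.ndarray, truth: np.ndarray
) -> ClassificationReport:
    """Accuracy/sensitivity/specificity/F-score (percent) and rank-based AUC.

    AUC is the Mann-Whitney statistic on the pooled decision scores (ties
    count one half); sensitivity is the patient-class recall.
    """
    confusion = np.asarray(confusion)
    (tn, fp), (fn, tp) = confusion
    n = confusion.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    truth = np.asarray(truth)
    if np.unique(truth).size < 2:
        raise ValueError("AUC undefined: only one class present in truth")
    acc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    spec = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = sens / 100.0
    f1 = 100.0 * (2 * prec * rec / (prec + rec)) if prec + rec else 0.0
    auc = float(roc_auc_score(truth, scores))
    fpr, tpr, _ = roc_curve(truth, scores)
    return ClassificationReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        f_score=f1,
        auc=auc,
        confusion=confusion,
        roc=np.column_stack([fpr, tpr]),
    )
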