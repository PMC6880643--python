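"""Size-penalized wrapper fitness.

A chromosome is scored on the attributes it expresses:

    f = (1 - r) * AC + r * (t - s) / t

where ``AC`` is the stratified cross-validated accuracy of a support-vector
classifier restricted to the expressed attributes, ``s`` is how many
attributes the chromosome expresses, ``t`` is the current terminal-set size
and ``r`` in [0, 0.5) trades accuracy against subset size. With ``r`` below
0.5 accuracy always dominates; the penalty merely breaks ties toward
smaller subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import clone
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, _libsvm

_libsvm.set_verbosity_wrap(0)

__all__ = [
    "ConfusionCounts",
    "FitnessRecord",
    "accuracy",
    "estimate_accuracy",
    "fitness",
    "default_classifier",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pooled binary confusion counts over held-out folds."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class FitnessRecord:
    """Evaluation result of one chromosome: accuracy, subset size, fitness."""

    AC: float
    s: int
    f: float


def accuracy(counts: ConfusionCounts) -> float:
    """Classification accuracy ``(TP + TN) / (TP + FN + TN + FP)``."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of zero evaluated samples")
    return (counts.tp + counts.tn) / counts.total


def default_classifier() -> SVC:
    """Linear-kernel SVM with default regularization (C = 1)."""
    return SVC(kernel="linear", C=1.0)


def _canonical_order(X: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Sample order independent of input row order: sort by class code then
    feature values, so fold assignment depends only on the data itself."""
    keys = tuple(X[:, j] for j in range(X.shape[1] - 1, -1, -1)) + (codes,)
    return np.lexsort(keys)


def _cv_predict_codes_libsvm(Xc, codes, folds_iter) -> tuple[np.ndarray, list[float]]:
    """Cross-validated predictions through the low-level libsvm binding that
    :class:`~sklearn.svm.SVC` itself wraps, skipping the per-call estimator
    machinery. Exact same solver and settings as ``SVC(kernel='linear', C=1)``
    (class codes are pre-sorted, matching SVC's label encoding)."""
    yf = codes.astype(np.float64)
    preds = np.empty(len(yf), dtype=np.float64)
    fold_acc = []
    for train, test in folds_iter:
        model = _libsvm.fit(
            np.ascontiguousarray(Xc[train]), yf[train],
            svm_type=0, kernel="linear", C=1.0,
        )
        p = _libsvm.predict(
            np.ascontiguousarray(Xc[test]), *model[:7],
            svm_type=0, kernel="linear",
        )
        preds[test] = p
        fold_acc.append(float(np.mean(p == yf[test])))
    return preds.astype(int), fold_acc


def estimate_accuracy(
    X,
    y,
    cv_folds: int = 5,
    classifier=None,
    seed: int = 0,
    return_counts: bool = True,
) -> tuple[float, ConfusionCounts | None]:
    """Mean accuracy of a support-vector classifier under stratified k-fold
    cross-validation, plus pooled confusion counts (binary problems only;
    ``None`` for more than two classes or when ``return_counts`` is off).

    Folds are built from a seeded shuffle of a canonical sample order, so
    the estimate is deterministic given ``seed`` and invariant to the order
    in which samples are supplied. If some class has fewer members than
    ``cv_folds``, the fold count is reduced to the smallest class size.

    With the default classifier (linear-kernel SVM, C=1) the fits go
    through libsvm directly, which matters because a selection run scores
    thousands of candidate subsets; any user-supplied scikit-learn
    estimator is cloned and fitted per fold instead.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"{X.shape[0]} samples but {y.shape[0]} labels")
    if X.shape[1] == 0:
        raise ValueError("attribute subset is empty")
    classes, codes, counts = np.unique(y, return_inverse=True, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to estimate accuracy")
    min_class = int(counts.min())
    if min_class < 2:
        raise ValueError("each class needs at least 2 samples for CV")
    folds = min(cv_folds, min_class)
    if folds < cv_folds:
        logger.info(
            "reducing CV folds from %d to %d (smallest class has %d samples)",
            cv_folds,
            folds,
            min_class,
        )

    order = _canonical_order(X, codes)
    Xc, yc, cc = X[order], y[order], codes[order]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    if classifier is None:
        pred_codes, fold_acc = _cv_predict_codes_libsvm(
            Xc, cc, skf.split(Xc, cc)
        )
        preds = classes[pred_codes]
    else:
        preds = np.empty_like(yc)
        fold_acc = []
        for train, test in skf.split(Xc, yc):
            clf = clone(classifier)
            clf.fit(Xc[train], yc[train])
            p = clf.predict(Xc[test])
            preds[test] = p
            fold_acc.append(float(np.mean(p == yc[test])))
    ac = float(np.mean(fold_acc))

    pooled = None
    if return_counts and classes.size == 2:
        # classes sorted by np.unique; the second is the "positive" class
        tn, fp, fn, tp = confusion_matrix(yc, preds, labels=list(classes)).ravel()
        pooled = ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
    return ac, pooled


def fitness(AC: float, s: int, t: int, r: float) -> float:
    """Combined fitness ``(1 - r) * AC + r * (t - s) / t``.

    ``s`` may exceed ``t``: a chromosome carried over from a larger pool can
    express more attributes than the pool now holds, in which case the
    penalty term goes negative and selection drives it out.
    """
    if not 0.0 <= r < 0.5:
        raise ValueError(f"r must lie in [0, 0.5), got {r}")
    if not 0.0 <= AC <= 1.0:
        raise ValueError(f"AC must lie in [0, 1], got {AC}")
    if s < 1 or t < 1:
        raise ValueError(f"need s >= 1 and t >= 1, got s={s}, t={t}")
    return (1.0 - r) * AC + r * (t - s) / t
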