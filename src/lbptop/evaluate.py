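"""Classifiers, cross-validation harness, and connectivity reference features.

The main evaluation protocol is outer 10-fold cross-validation: subjects are
randomly partitioned into balanced folds; each fold is held out once while a
linear SVM (penalty C grid-searched by an internal 10-fold CV on the
training split only) or a 1-nearest-neighbor classifier is trained on the
rest; the pooled held-out predictions give the accuracy.  Optional feature
selection is fit inside each training split, never on held-out data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import clone
from sklearn.metrics import confusion_matrix
from sklearn.svm import LinearSVC

from .selection import DEFAULT_C_GRID

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """A fixed assignment of subjects to cross-validation folds."""

    n_folds: int
    seed: int
    assignment: dict  # subject id -> fold id

    def fold_members(self, fold: int):
        return [s for s, f in self.assignment.items() if f == fold]


def make_cv_plan(subject_ids, n_folds: int = 10, seed: int = 0, stratify_labels=None) -> CVPlan:
    """Seeded random partition into folds whose sizes differ by at most one.

    Default is an unstratified shuffle; pass per-subject ``stratify_labels``
    to balance classes across folds instead.
    """
    subject_ids = list(subject_ids)
    N = len(subject_ids)
    if N < n_folds:
        raise ValueError(f"cannot split {N} subjects into {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignment = {}
    if stratify_labels is None:
        order = rng.permutation(N)
        for pos, idx in enumerate(order):
            assignment[subject_ids[idx]] = pos % n_folds
    else:
        stratify_labels = np.asarray(list(stratify_labels))
        pos = 0
        for cls in np.unique(stratify_labels):
            members = [i for i, lab in enumerate(stratify_labels) if lab == cls]
            for idx in rng.permutation(members):
                assignment[subject_ids[idx]] = pos % n_folds
                pos += 1
    return CVPlan(n_folds=n_folds, seed=seed, assignment=assignment)


def train_linear_svm(X, y, C: float = 1.0) -> LinearSVC:
    """Fit a liblinear-backed linear SVM (deterministic: primal, fixed tol).

    The fitted model's decision is sign(w.x + b) mapped to the two classes,
    with w in ``coef_`` and b in ``intercept_``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = LinearSVC(C=C, loss="squared_hinge", dual=False, tol=1e-6, max_iter=20000)
    model.fit(X, y)
    return model


def grid_search_C(X, y, grid=DEFAULT_C_GRID, n_folds: int = 10, seed: int = 0):
    """Pick the penalty C maximizing internal-CV accuracy; ties -> smallest C.

    The internal folds are computed on the given (training) data only.
    Returns (best_C, {C: accuracy}).
    """
    grid = sorted(float(c) for c in grid)
    if not grid:
        raise ValueError("empty C grid")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = len(y)
    folds = min(n_folds, n)
    plan = make_cv_plan(range(n), n_folds=folds, seed=seed)
    fold_of = np.array([plan.assignment[i] for i in range(n)])
    accs = {}
    for C in grid:
        correct = 0
        for f in range(folds):
            tr, te = fold_of != f, fold_of == f
            if len(np.unique(y[tr])) < 2:
                continue
            m = train_linear_svm(X[tr], y[tr], C)
            correct += int(np.sum(m.predict(X[te]) == y[te]))
        accs[C] = correct / n
    best_C = max(grid, key=lambda c: (accs[c], -c))
    return best_C, accs


def make_svm_trainer(C_grid=DEFAULT_C_GRID, inner_folds: int = 10):
    """Trainer contract for the group selector: grid-search then fit."""

    def trainer(X, y, seed):
        best_C, _ = grid_search_C(X, y, C_grid, n_folds=inner_folds, seed=seed)
        return train_linear_svm(X, y, best_C)

    return trainer


def knn_predict(train_X, train_y, test_X, K: int = 1) -> np.ndarray:
    """1-nearest-neighbor prediction, Euclidean metric.

    Distance ties resolve to the lowest training-row index.
    """
    if K != 1:
        raise ValueError("only K = 1 is supported")
    train_X = np.atleast_2d(np.asarray(train_X, dtype=np.float64))
    test_X = np.atleast_2d(np.asarray(test_X, dtype=np.float64))
    train_y = np.asarray(train_y)
    if train_X.shape[0] == 0:
        raise ValueError("empty training set")
    d = cdist(test_X, train_X)  # argmin returns the first minimum -> tie rule
    return train_y[np.argmin(d, axis=1)]


@dataclass
class EvalResult:
    """Pooled held-out predictions from one cross-validated evaluation."""

    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float
    confusion: np.ndarray  # 2x2, rows = true class, cols = predicted
    classes: np.ndarray
    fold_of: np.ndarray
    per_fold_C: list = field(default_factory=list)
    per_fold_survivors: list = field(default_factory=list)

    @property
    def error(self) -> float:
        return 1.0 - self.accuracy


def cross_validate(
    X,
    y,
    plan: CVPlan,
    classifier: str = "svm",
    selector=None,
    C_grid=DEFAULT_C_GRID,
    inner_folds: int = 10,
    reuse_C: float | None = None,
) -> EvalResult:
    """Run the outer CV protocol and pool held-out predictions.

    ``selector`` (any sklearn selector, e.g.
    :class:`~lbptop.selection.IterativeSVMGroupSelector`) is cloned and fit
    on each training split before the classifier sees the data.  ``reuse_C``
    skips the per-fold grid search and trains every fold at the given C (a
    fast path for permutation replicates).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n = len(y)
    ids = sorted(plan.assignment)
    if len(ids) != n:
        raise ValueError(f"plan covers {len(ids)} subjects but y has {n}")
    fold_of = np.array([plan.assignment[i] for i in ids])
    classes = np.unique(y)

    y_pred = np.empty(n, dtype=y.dtype)
    per_fold_C, per_fold_surv = [], []
    for f in range(plan.n_folds):
        tr, te = fold_of != f, fold_of == f
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"training split of fold {f} contains a single class")
        X_tr, X_te = X[tr], X[te]
        if selector is not None:
            sel = clone(selector)
            sel.fit(X_tr, y[tr])
            X_tr, X_te = sel.transform(X_tr), sel.transform(X_te)
            per_fold_surv.append(X_tr.shape[1])
        if classifier == "svm":
            if reuse_C is not None:
                best_C = float(reuse_C)
            else:
                best_C, _ = grid_search_C(X_tr, y[tr], C_grid, n_folds=inner_folds,
                                          seed=plan.seed * plan.n_folds + f + 1)
            per_fold_C.append(best_C)
            model = train_linear_svm(X_tr, y[tr], best_C)
            y_pred[te] = model.predict(X_te)
        elif classifier == "knn":
            y_pred[te] = knn_predict(X_tr, y[tr], X_te, K=1)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        logger.info("fold %d: %d train / %d test", f, int(tr.sum()), int(te.sum()))

    acc = float(np.mean(y_pred == y))
    conf = confusion_matrix(y, y_pred, labels=classes)
    return EvalResult(y_true=y, y_pred=y_pred, accuracy=acc, confusion=conf,
                      classes=classes, fold_of=fold_of,
                      per_fold_C=per_fold_C, per_fold_survivors=per_fold_surv)


def connectivity_features(timecourses: np.ndarray):
    """Pairwise Pearson correlations between region timecourses.

    ``timecourses`` is regions x timepoints.  Returns (values, pairs) with
    one value per unordered region pair (i, j), i < j, lexicographic order;
    length n(n-1)/2 (6670 for the 116-region AAL parcellation).
    """
    tc = np.asarray(timecourses, dtype=np.float64)
    if tc.ndim != 2 or tc.shape[0] < 2:
        raise ValueError("need a 2D regions x timepoints array with >= 2 regions")
    if tc.shape[1] < 3:
        raise ValueError("need >= 3 timepoints")
    variances = tc.var(axis=1)
    dead = np.flatnonzero(variances == 0)
    if dead.size:
        raise ValueError(f"zero-variance region(s): {dead.tolist()}")
    corr = np.corrcoef(tc)
    iu, ju = np.triu_indices(tc.shape[0], k=1)
    return corr[iu, ju], list(zip(iu.tolist(), ju.tolist()))
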