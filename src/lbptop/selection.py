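"""Iterative SVM-weight feature selection across feature groups.

Feature groups (e.g. one LBP-TOP radius, or one parcellation x radius) are
merged one at a time: after appending a group, a linear SVM is grid-searched
for its penalty C by internal 10-fold cross-validation, fit, and the worse
half of the current columns (ranked by |w|) is dropped.  Groups flagged as
whole-brain-scale are appended without the drop, because a whole-brain-mask
histogram already has few features.  Selection always runs on training data
only; nest it inside each outer CV fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = tuple(2.0 ** np.arange(-10, 11))


@dataclass
class FeatureGroupSet:
    """Ordered named feature blocks over the same subjects, plus class labels.

    ``matrices`` are disjoint column blocks (subjects x n_k each);
    ``whole_brain`` flags groups exempt from the drop step.
    """

    names: list
    matrices: list
    labels: np.ndarray = None
    whole_brain: list = None

    def __post_init__(self):
        if self.whole_brain is None:
            self.whole_brain = [False] * len(self.matrices)
        if not (len(self.names) == len(self.matrices) == len(self.whole_brain)):
            raise ValueError("names, matrices and whole_brain flags must align")
        n_rows = {m.shape[0] for m in self.matrices}
        if len(n_rows) > 1:
            raise ValueError(f"groups disagree on subject count: {sorted(n_rows)}")

    @property
    def sizes(self):
        return [m.shape[1] for m in self.matrices]

    def concatenated(self) -> np.ndarray:
        return np.hstack(self.matrices)

    def slices(self):
        out, start = [], 0
        for m in self.matrices:
            out.append(slice(start, start + m.shape[1]))
            start += m.shape[1]
        return out


def rank_by_weight(w: np.ndarray) -> np.ndarray:
    """Feature indices by descending |w|; ties broken by ascending index."""
    w = np.asarray(w, dtype=np.float64).ravel()
    if w.size == 0:
        raise ValueError("empty weight vector (untrained model?)")
    return np.lexsort((np.arange(w.size), -np.abs(w)))


def keep_top_half(ordering: np.ndarray, n_features: int) -> np.ndarray:
    """First ceil(n/2) indices of the ranking (the retained set)."""
    ordering = np.asarray(ordering)
    if sorted(ordering.tolist()) != list(range(n_features)):
        raise ValueError("ordering is not a permutation of 0..n_features-1")
    keep = int(np.ceil(n_features / 2))
    return ordering[:keep]


def survivor_counts(group_sizes, whole_brain_flags=None):
    """Closed-form survivor cardinalities: s_k = ceil((s_{k-1}+n_k)/2), no drop for flagged groups."""
    if whole_brain_flags is None:
        whole_brain_flags = [False] * len(group_sizes)
    s, out = 0, []
    for n_k, flag in zip(group_sizes, whole_brain_flags):
        s = s + n_k if flag else int(np.ceil((s + n_k) / 2))
        out.append(s)
    return out


def combine_groups(group_set: FeatureGroupSet, y, trainer, seed: int = 0):
    """Merge groups per the iterative halving procedure.

    ``trainer(X, y, seed)`` must grid-search C on the given training data
    only and return a fitted model exposing ``coef_`` (shape (1, n_features))
    — see :func:`lbptop.evaluate.make_svm_trainer`.  Returns
    ``(selected, X_selected, history)`` where ``selected`` is an array of
    column positions into the concatenated group matrix, in ascending order,
    and history records per-iteration survivor counts and chosen C.
    """
    if len(group_set.matrices) == 0:
        raise ValueError("need at least one feature group")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    for name, m in zip(group_set.names, group_set.matrices):
        if m.shape[1] == 0:
            raise ValueError(f"group {name!r} is empty")

    slices = group_set.slices()
    current = np.empty(0, dtype=np.intp)  # column ids into the concatenated matrix
    X_all = group_set.concatenated()
    history = []
    for k, (name, sl, flag) in enumerate(zip(group_set.names, slices, group_set.whole_brain)):
        current = np.concatenate([current, np.arange(sl.start, sl.stop, dtype=np.intp)])
        X_cur = X_all[:, current]
        model = trainer(X_cur, y, seed + k)
        if not flag:
            order = rank_by_weight(model.coef_.ravel())
            kept = keep_top_half(order, X_cur.shape[1])
            current = np.sort(current[kept])
        history.append(
            {"group": name, "n_after": int(current.size),
             "C": float(getattr(model, "C", np.nan)), "dropped": not flag}
        )
        logger.info("group %s merged: %d survivors", name, current.size)
    return current, X_all[:, current], history


class IterativeSVMGroupSelector(SelectorMixin, BaseEstimator):
    """Scikit-learn transformer wrapping the group-merging selection.

    Parameters
    ----------
    group_sizes : sequence of int
        Column counts of the ordered groups inside the concatenated input
        matrix (columns 0..n_1-1 are group 1, and so on).
    whole_brain : sequence of bool, optional
        Per-group exemption from the drop step.
    C_grid : sequence of float
        Candidate SVM penalties, searched by internal CV each iteration.
    inner_folds : int
        Folds of the internal grid-search CV.
    seed : int
        Seed for the internal CV plans; selection is deterministic given it.

    Attributes
    ----------
    support_ : boolean mask over input columns, True for survivors.
    selected_ : ascending array of surviving column indices.
    history_ : per-iteration survivor counts and chosen C.
    """

    def __init__(self, group_sizes=None, whole_brain=None,
                 C_grid=DEFAULT_C_GRID, inner_folds=10, seed=0):
        self.group_sizes = group_sizes
        self.whole_brain = whole_brain
        self.C_grid = C_grid
        self.inner_folds = inner_folds
        self.seed = seed

    def fit(self, X, y):
        from .evaluate import make_svm_trainer

        X = validate_data(self, X, ensure_2d=True, dtype=np.float64, reset=True)
        y = np.asarray(y)
        sizes = list(self.group_sizes) if self.group_sizes is not None else [X.shape[1]]
        if sum(sizes) != X.shape[1]:
            raise ValueError(f"group sizes {sizes} do not sum to {X.shape[1]} columns")
        flags = list(self.whole_brain) if self.whole_brain is not None else None
        start, mats = 0, []
        for n_k in sizes:
            mats.append(X[:, start : start + n_k])
            start += n_k
        gs = FeatureGroupSet(
            names=[f"g{k}" for k in range(len(mats))], matrices=mats, whole_brain=flags
        )
        trainer = make_svm_trainer(self.C_grid, self.inner_folds)
        selected, _, history = combine_groups(gs, y, trainer, seed=self.seed)
        self.selected_ = selected
        self.history_ = history
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[selected] = True
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
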