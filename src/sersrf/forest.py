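"""Classification forests plus the tree-level quantities the selection,
relation and group methods need: out-of-bag (OOB) and hold-out permutation
importance, surrogate splits with adjusted agreement, first-appearance
(minimal) depths, and Monte-Carlo null-depth thresholds.

Forest induction delegates to scikit-learn; everything else (bootstrap /
OOB bookkeeping, surrogates, importances, depths) is computed here from
the exported tree structures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from ._kernels import (
    build_node_samples,
    null_depth_mean,
    predict_rows,
    tree_permutation_importance,
    tree_surrogates,
)

__all__ = [
    "ForestParams",
    "ForestModel",
    "ImportanceResult",
    "default_mtry",
    "default_surrogate_count",
    "fit_forest",
    "permutation_importance",
    "holdout_importance",
    "find_surrogates",
    "first_appearance_depths",
    "null_depth_threshold",
]


def default_mtry(p: int) -> int:
    """Candidate variables per node: floor(p^(3/4)) (228 for p=1401)."""
    return int(np.floor(p ** 0.75))


def default_surrogate_count(p: int) -> int:
    """Surrogates stored per node: floor(0.05 p) (70 for p=1401)."""
    return max(1, int(np.floor(0.05 * p)))


@dataclass
class ForestParams:
    """Forest hyperparameters.

    ``ntree`` defaults to the full-scale study value for the selection
    methods; callers scale it down for desk-size runs.  ``mtry=None``
    resolves to ``floor(p^(3/4))`` at fit time.
    """

    ntree: int = 10000
    mtry: int | None = None
    nodesize: int = 1

    def resolve_mtry(self, p: int) -> int:
        m = default_mtry(p) if self.mtry is None else self.mtry
        return int(min(max(m, 1), p))


@dataclass
class ImportanceResult:
    """Per-variable permutation importance (mean accuracy decrease)."""

    values: np.ndarray
    variant: str  # "oob" or "holdout"


@dataclass
class _TreeArrays:
    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    leaf_code: np.ndarray
    depth: np.ndarray
    max_depth: int
    boot_idx: np.ndarray
    oob_idx: np.ndarray

    @property
    def internal(self) -> np.ndarray:
        return self.children_left >= 0


def _node_depths(cl: np.ndarray, cr: np.ndarray) -> np.ndarray:
    depth = np.zeros(cl.shape[0], dtype=np.int64)
    for nd in range(cl.shape[0]):  # parents precede children in the layout
        if cl[nd] >= 0:
            depth[cl[nd]] = depth[nd] + 1
            depth[cr[nd]] = depth[nd] + 1
    return depth


class ForestModel:
    """A fitted forest with exported tree structure and sample bookkeeping.

    Wraps a fitted ``RandomForestClassifier``; bootstrap indices are
    re-derived from each tree's integer seed with the same draw the
    library uses (``RandomState(seed).randint(0, n, n)``).
    """

    def __init__(self, sk_forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray):
        self.sk_forest = sk_forest
        self.X = np.ascontiguousarray(X, dtype=np.float64)
        self.classes_ = sk_forest.classes_
        self.y_codes = np.searchsorted(self.classes_, y).astype(np.int8)
        n = X.shape[0]
        self.n_samples = n
        self.n_features = X.shape[1]
        self.trees: list[_TreeArrays] = []
        all_idx = np.arange(n)
        for est in sk_forest.estimators_:
            t = est.tree_
            cl = t.children_left.astype(np.int64)
            cr = t.children_right.astype(np.int64)
            depth = _node_depths(cl, cr)
            boot = np.random.RandomState(est.random_state).randint(0, n, n)
            oob = all_idx[~np.isin(all_idx, boot)]
            self.trees.append(
                _TreeArrays(
                    children_left=cl,
                    children_right=cr,
                    feature=t.feature.astype(np.int64),
                    threshold=t.threshold.astype(np.float64),
                    leaf_code=np.argmax(t.value[:, 0, :], axis=1).astype(np.int8),
                    depth=depth,
                    max_depth=int(depth.max()),
                    boot_idx=boot.astype(np.int64),
                    oob_idx=oob.astype(np.int64),
                )
            )
        self.node_samples_: list[tuple[np.ndarray, np.ndarray]] | None = None
        self.surrogates_: list[tuple[np.ndarray, np.ndarray]] | None = None
        self.surrogate_s_: int | None = None

    @property
    def ntree(self) -> int:
        return len(self.trees)

    def ensure_node_samples(self) -> None:
        if self.node_samples_ is None:
            self.node_samples_ = [
                build_node_samples(
                    t.children_left, t.children_right, t.feature, t.threshold,
                    self.X, t.boot_idx,
                )
                for t in self.trees
            ]

    def oob_error(self) -> float:
        """Ensemble OOB misclassification rate (majority vote over trees)."""
        votes = np.zeros((self.n_samples, len(self.classes_)))
        for t in self.trees:
            if t.oob_idx.size == 0:
                continue
            pred = predict_rows(
                t.children_left, t.children_right, t.feature, t.threshold,
                t.leaf_code, self.X, t.oob_idx,
            )
            np.add.at(votes, (t.oob_idx, pred.astype(np.int64)), 1.0)
        covered = votes.sum(axis=1) > 0
        if not covered.any():
            raise RuntimeError("no sample has OOB predictions; increase ntree")
        pred_code = votes[covered].argmax(axis=1)
        return float(np.mean(pred_code != self.y_codes[covered]))


def fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    params: ForestParams | None = None,
    random_state: int = 0,
) -> ForestModel:
    """Fit a bootstrap classification forest (Gini splits).

    Raises on single-class labels or non-finite inputs.
    """
    params = params or ForestParams()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    rf = RandomForestClassifier(
        n_estimators=params.ntree,
        max_features=params.resolve_mtry(X.shape[1]),
        min_samples_leaf=params.nodesize,
        criterion="gini",
        bootstrap=True,
        n_jobs=1,
        random_state=random_state,
    )
    rf.fit(X, y)
    return ForestModel(rf, X, y)


def _importance_over_trees(
    model: ForestModel, rows_per_tree: Sequence[np.ndarray], seed: int
) -> np.ndarray:
    """Mean per-tree accuracy drop.  Permutation protocol: per tree ``t``
    a ``default_rng(SeedSequence([seed, t]))`` draws one permutation of the
    evaluation rows for each variable used in the tree, in ascending
    variable order."""
    imp = np.zeros(model.n_features)
    for t_idx, t in enumerate(model.trees):
        rows = rows_per_tree[t_idx]
        if rows.size == 0:
            continue
        used = np.unique(t.feature[t.feature >= 0])
        if used.size == 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, t_idx]))
        perms = np.empty((used.size, rows.size), dtype=np.int64)
        for j in range(used.size):
            perms[j] = rng.permutation(rows.size)
        _, drops = tree_permutation_importance(
            t.children_left, t.children_right, t.feature, t.threshold,
            t.leaf_code, model.X, rows.astype(np.int64), model.y_codes,
            used.astype(np.int64), perms,
        )
        imp[used] += drops
    return imp / model.ntree


def permutation_importance(model: ForestModel, seed: int = 0) -> ImportanceResult:
    """OOB permutation importance: mean over trees of the OOB accuracy
    decrease after permuting one variable's OOB values."""
    rows = [t.oob_idx for t in model.trees]
    return ImportanceResult(_importance_over_trees(model, rows, seed), "oob")


def holdout_importance(
    X: np.ndarray,
    y: np.ndarray,
    params: ForestParams | None = None,
    random_state: int = 0,
    max_attempts: int = 10,
) -> ImportanceResult:
    """Hold-out permutation importance (the Vita variant).

    The data are split into two stratified halves; one forest is fitted
    per half and each variable's importance is evaluated on the opposite
    half (for every tree); the two results are averaged.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples for hold-out importance")
    for attempt in range(max_attempts):
        seed = random_state + attempt
        splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.5, random_state=seed)
        idx_a, idx_b = next(splitter.split(X, y))
        if np.unique(y[idx_a]).size == 2 and np.unique(y[idx_b]).size == 2:
            break
    else:
        raise RuntimeError("could not split data into two-class folds")
    imp = np.zeros(X.shape[1])
    for fold_train, fold_eval, sub in ((idx_a, idx_b, 1), (idx_b, idx_a, 2)):
        # fit on the union so row indices stay global: fit on the fold only
        model = fit_forest(X[fold_train], y[fold_train], params, random_state=seed + sub)
        # evaluate on the opposite fold: build an eval view
        eval_model = _reindex_for_eval(model, X[fold_eval], y[fold_eval])
        rows = [np.arange(fold_eval.size)] * eval_model.ntree
        imp += _importance_over_trees(eval_model, rows, seed=seed + 10 * sub)
    return ImportanceResult(imp / 2.0, "holdout")


def _reindex_for_eval(model: ForestModel, X_eval: np.ndarray, y_eval: np.ndarray) -> ForestModel:
    """Shallow copy of a fitted model whose data matrix is the hold-out fold."""
    clone = ForestModel.__new__(ForestModel)
    clone.sk_forest = model.sk_forest
    clone.X = np.ascontiguousarray(X_eval, dtype=np.float64)
    clone.classes_ = model.classes_
    clone.y_codes = np.searchsorted(model.classes_, y_eval).astype(np.int8)
    clone.n_samples = X_eval.shape[0]
    clone.n_features = X_eval.shape[1]
    clone.trees = model.trees
    clone.node_samples_ = None
    clone.surrogates_ = None
    clone.surrogate_s_ = None
    return clone


def find_surrogates(
    model: ForestModel,
    s: int | None = None,
    candidates: np.ndarray | None = None,
    targets: np.ndarray | None = None,
) -> ForestModel:
    """Compute per-node surrogate splits (top ``s`` by adjusted agreement).

    For every internal node and every non-primary candidate variable, the
    split point maximizing agreement with the primary partition over the
    node's bootstrap samples is found; adjusted agreement is
    ``(matches - majority) / (n_node - majority)``.  Non-positive values
    disqualify a surrogate.  ``candidates`` restricts the searched
    variables and ``targets`` restricts the searched nodes to those whose
    primary split is a target (both used by the relation analysis);
    defaults cover all variables and nodes.  Results are stored on the
    model (``surrogates_``) and the model is returned.
    """
    p = model.n_features
    if candidates is None:
        candidates = np.arange(p)
    candidates = np.asarray(candidates, dtype=np.int64)
    if s is None:
        s = default_surrogate_count(p)
    s = int(min(max(s, 1), max(candidates.size - 1, 1)))
    target_mask = None
    if targets is not None:
        target_mask = np.zeros(p, dtype=bool)
        target_mask[np.asarray(targets, dtype=np.int64)] = True
    model.ensure_node_samples()
    model.surrogates_ = []
    for t, (start, samples) in zip(model.trees, model.node_samples_):
        if target_mask is None:
            node_mask = np.ones(t.children_left.shape[0], dtype=np.bool_)
        else:
            node_mask = np.zeros(t.children_left.shape[0], dtype=np.bool_)
            internal = t.children_left >= 0
            node_mask[internal] = target_mask[t.feature[internal]]
        sv, sa = tree_surrogates(
            t.children_left, t.children_right, t.feature, t.threshold,
            model.X, start, samples, candidates, node_mask, s,
        )
        model.surrogates_.append((sv, sa))
    model.surrogate_s_ = s
    return model


def first_appearance_depths(
    model: ForestModel, include_surrogates: bool = False
) -> np.ndarray:
    """Mean depth of first appearance per variable (minimal depth).

    Per tree, a variable's depth is that of the shallowest node where it
    is the primary split (or, with ``include_surrogates``, primary or
    surrogate); variables absent from a tree get that tree's max depth
    plus one.  The average over trees is returned.
    """
    if include_surrogates and model.surrogates_ is None:
        raise RuntimeError("call find_surrogates() before surrogate depths")
    p = model.n_features
    total = np.zeros(p)
    for t_idx, t in enumerate(model.trees):
        depths = np.full(p, t.max_depth + 1, dtype=np.float64)
        internal = t.internal
        np.minimum.at(depths, t.feature[internal], t.depth[internal].astype(float))
        if include_surrogates:
            sv, _ = model.surrogates_[t_idx]
            node_depth = np.repeat(t.depth.astype(float), sv.shape[1]).reshape(sv.shape)
            valid = sv >= 0
            np.minimum.at(depths, sv[valid], node_depth[valid])
        total += depths
    return total / model.ntree


def null_depth_threshold(
    model: ForestModel,
    t: float = 1.0,
    include_surrogates: bool = False,
    s: int | None = None,
    n_randomizations: int = 20,
    seed: int = 0,
) -> float:
    """Monte-Carlo selection threshold for (surrogate) minimal depth.

    Keeps each realized tree topology and re-assigns every internal
    node's primary variable uniformly at random over all ``p`` variables
    (plus ``s`` distinct surrogate variables per node when
    ``include_surrogates``); the mean first-appearance depth over all
    variables, averaged over ``n_randomizations`` randomizations, times
    the user factor ``t`` is returned.  Variables with observed depth
    strictly below the threshold count as selected.
    """
    p = model.n_features
    if s is None:
        s = model.surrogate_s_ or default_surrogate_count(p)
    s = int(min(s, p - 1))
    depths_list = [tr.depth[tr.internal] for tr in model.trees]
    tree_ptr = np.zeros(model.ntree + 1, dtype=np.int64)
    for i, d in enumerate(depths_list):
        tree_ptr[i + 1] = tree_ptr[i] + d.size
    internal_depth = (
        np.concatenate(depths_list).astype(np.float64)
        if tree_ptr[-1] > 0
        else np.zeros(0)
    )
    penalty = np.array([tr.max_depth + 1 for tr in model.trees], dtype=np.float64)
    mean_null = null_depth_mean(
        internal_depth, tree_ptr, penalty, p, s,
        include_surrogates, n_randomizations, seed % (2**31),
    )
    return float(t * mean_null)
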