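"""Variable-relation analysis via mean adjusted agreement.

The surrogate-split machinery yields, per tree node, how well each other
variable can mimic the node's primary split (adjusted agreement).
Averaging a candidate's adjusted agreement over all nodes whose primary
split is a given target variable — counting zero where the candidate is
not among the node's stored surrogates — gives the (asymmetric) *mean
adjusted agreement* relation measure.  Values above a null threshold
(random surrogate identities on the same forest) mark related variables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .forest import ForestModel, ForestParams, find_surrogates, fit_forest

__all__ = [
    "RelationResult",
    "RelationFrequencyMatrix",
    "mean_adjusted_agreement",
    "relation_threshold",
    "cluster_order",
    "VariableRelations",
    "relation_frequency_over_replicates",
]


@dataclass
class RelationResult:
    targets: np.ndarray
    candidates: np.ndarray
    matrix: np.ndarray  # (targets x candidates), self entries NaN
    threshold: float
    related: np.ndarray  # boolean, NaN entries False


@dataclass
class RelationFrequencyMatrix:
    """Per-pair detection proportion over replicates, with cluster ordering."""

    targets: np.ndarray
    frequencies: np.ndarray
    thresholds: list[float]
    row_order: np.ndarray | None = None
    col_order: np.ndarray | None = None


def _accumulate(model: ForestModel, targets: np.ndarray, candidates: np.ndarray):
    """Sum of stored adjusted agreements per (target, candidate) and the
    number of nodes whose primary split is each target."""
    if model.surrogates_ is None:
        raise RuntimeError("call find_surrogates() before relation analysis")
    p = model.n_features
    tpos = np.full(p, -1, dtype=np.int64)
    tpos[targets] = np.arange(targets.size)
    cpos = np.full(p, -1, dtype=np.int64)
    cpos[candidates] = np.arange(candidates.size)
    sums = np.zeros((targets.size, candidates.size))
    counts = np.zeros(targets.size, dtype=np.int64)
    for t, (sv, sa) in zip(model.trees, model.surrogates_):
        internal = np.flatnonzero(t.internal)
        prim = t.feature[internal]
        sel = tpos[prim] >= 0
        for nd, j in zip(internal[sel], tpos[prim[sel]]):
            counts[j] += 1
            for r in range(sv.shape[1]):
                v = sv[nd, r]
                if v < 0:
                    break
                ci = cpos[v]
                if ci >= 0:
                    sums[j, ci] += sa[nd, r]
    return sums, counts


def mean_adjusted_agreement(
    model: ForestModel,
    targets: Sequence[int],
    candidates: Sequence[int] | None = None,
) -> np.ndarray:
    """Mean adjusted agreement matrix (targets x candidates).

    Entry (j, i) averages candidate i's adjusted agreement over all nodes
    with primary split on target j (zero when i is not among the node's
    surrogates); targets that never appear as primary yield a zero row.
    Target-candidate pairs referring to the same variable are NaN.
    """
    targets = np.asarray(targets, dtype=np.int64)
    if candidates is None:
        candidates = np.arange(model.n_features)
    candidates = np.asarray(candidates, dtype=np.int64)
    sums, counts = _accumulate(model, targets, candidates)
    denom = np.maximum(counts, 1)[:, None].astype(float)
    matrix = sums / denom
    for j, tv in enumerate(targets):
        hit = np.flatnonzero(candidates == tv)
        matrix[j, hit] = np.nan
    return matrix


def relation_threshold(
    model: ForestModel,
    targets: Sequence[int],
    candidates: Sequence[int] | None = None,
    t: float = 1.0,
) -> float:
    """Null threshold: expected mean adjusted agreement when surrogate
    identities are re-assigned at random.

    Re-assigning each node's stored agreements to random distinct
    non-primary variables of the candidate universe leaves every row sum
    of the relation matrix unchanged, so the mean of the randomized
    matrix has the closed form ``sum_j (S_j / N_j) / sum_j (|C| - 1)``
    (``S_j``: total stored agreement at nodes with primary j, ``N_j``:
    number of such nodes); the Monte-Carlo average of the stated
    randomization converges to exactly this value, which is returned
    times the factor ``t``.
    """
    targets = np.asarray(targets, dtype=np.int64)
    if candidates is None:
        candidates = np.arange(model.n_features)
    candidates = np.asarray(candidates, dtype=np.int64)
    sums, counts = _accumulate(model, targets, candidates)
    row_mass = sums.sum(axis=1) / np.maximum(counts, 1)
    n_excl = np.array(
        [candidates.size - (1 if tv in set(candidates.tolist()) else 0) for tv in targets],
        dtype=float,
    )
    total_cells = n_excl.sum()
    if total_cells == 0:
        return 0.0
    return float(t * row_mass.sum() / total_cells)


def cluster_order(matrix: np.ndarray, k: int, random_state: int = 0) -> np.ndarray:
    """Row permutation grouping k-means clusters (Euclidean) contiguously.

    Clusters keep their order of first appearance; rows keep their
    original order within a cluster.  Apply to the transpose for columns.
    ``k=1`` returns the identity order.
    """
    n = matrix.shape[0]
    if k < 1 or k > n:
        raise ValueError("k must be in [1, n]")
    if k == 1:
        return np.arange(n)
    clean = np.nan_to_num(np.asarray(matrix, dtype=float), nan=0.0)
    labels = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(clean)
    order = []
    for lab in dict.fromkeys(labels.tolist()):
        order.extend(np.flatnonzero(labels == lab).tolist())
    return np.asarray(order)


class VariableRelations(BaseEstimator):
    """Relation analysis on one dataset.

    Fits a forest, searches surrogates restricted to the declared
    candidate universe at nodes whose primary split is a target, and
    thresholds the mean adjusted agreement matrix.
    """

    def __init__(
        self,
        targets: Sequence[int],
        candidates: Sequence[int] | None = None,
        ntree: int = 1000,
        mtry: int | None = None,
        s: int | None = None,
        t: float = 1.0,
        random_state: int = 0,
    ):
        self.targets = targets
        self.candidates = candidates
        self.ntree = ntree
        self.mtry = mtry
        self.s = s
        self.t = t
        self.random_state = random_state

    def fit(self, X, y, model: ForestModel | None = None):
        targets = np.asarray(self.targets, dtype=np.int64)
        if model is None:
            model = fit_forest(
                X, y, ForestParams(ntree=self.ntree, mtry=self.mtry),
                random_state=self.random_state,
            )
        candidates = (
            np.arange(model.n_features)
            if self.candidates is None
            else np.asarray(self.candidates, dtype=np.int64)
        )
        # The surrogate search and the null threshold must run over the
        # full variable universe: restricting them to the reported
        # candidates would make the randomized-null mean coincide with
        # the observed mean (every node's agreement mass lands inside
        # the candidate set either way) and the threshold degenerate.
        # Only nodes whose primary split is a target need searching.
        find_surrogates(model, s=self.s, targets=targets)
        self.matrix_ = mean_adjusted_agreement(model, targets, candidates)
        self.threshold_ = relation_threshold(model, targets, None, t=self.t)
        with np.errstate(invalid="ignore"):
            self.related_ = self.matrix_ > self.threshold_
        self.model_ = model
        return self

    def result(self) -> RelationResult:
        return RelationResult(
            targets=np.asarray(self.targets),
            candidates=(
                np.arange(self.matrix_.shape[1])
                if self.candidates is None
                else np.asarray(self.candidates)
            ),
            matrix=self.matrix_,
            threshold=self.threshold_,
            related=self.related_,
        )


def relation_frequency_over_replicates(
    datasets,
    targets: Sequence[int],
    ntree: int = 1000,
    mtry: int | None = None,
    s: int | None = None,
    t: float = 1.0,
    k: int = 2,
    random_state: int = 0,
) -> RelationFrequencyMatrix:
    """Detection proportion of each pairwise relation over replicates.

    Per replicate a forest is fitted, the targets x targets relation
    matrix binarized at the null threshold, and the per-pair detection
    proportion returned; rows and columns are ordered by independent
    k-means clusterings.
    """
    datasets = list(datasets)
    targets = np.asarray(targets, dtype=np.int64)
    detections = np.zeros((targets.size, targets.size))
    thresholds = []
    for i, ds in enumerate(datasets):
        rel = VariableRelations(
            targets, candidates=targets, ntree=ntree, mtry=mtry, s=s, t=t,
            random_state=random_state + i,
        ).fit(ds.spectra, ds.labels)
        detections += np.where(np.isnan(rel.matrix_), 0.0, rel.related_.astype(float))
        thresholds.append(rel.threshold_)
    freq = detections / len(datasets)
    row_order = cluster_order(freq, min(k, targets.size), random_state)
    col_order = cluster_order(freq.T, min(k, targets.size), random_state)
    return RelationFrequencyMatrix(
        targets=targets,
        frequencies=freq,
        thresholds=thresholds,
        row_order=row_order,
        col_order=col_order,
    )
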