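"""Evaluation of predefined spectral variable groups.

Two pathway-guided forest methods:

* LeFE (Learner of Functional Enrichment), a *competing* method: forests
  are trained on the group's variables plus an equal number of randomly
  sampled outside variables, and a rank-sum test asks whether the group's
  importances exceed the outside importances.
* PE (prediction error), a *self-sufficient* method: a forest is trained
  on the group's variables only and its out-of-bag error is compared to
  an empirical null obtained by refitting on permuted labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .forest import ForestParams, fit_forest, permutation_importance
from .simulate import SingleSpectrum, band_membership

__all__ = [
    "GroupDefinition",
    "GroupParams",
    "GroupSelectionResult",
    "groups_from_library",
    "LeFESelector",
    "PredictionErrorSelector",
    "select_lefe",
    "select_pe",
]


@dataclass(frozen=True)
class GroupDefinition:
    """A named set of variable indices (e.g. the bands of one single spectrum)."""

    name: str
    indices: tuple[int, ...]

    def __post_init__(self):
        if len(self.indices) == 0:
            raise ValueError(f"group {self.name} is empty")


@dataclass
class GroupParams:
    """Full-scale defaults of the group methods (Table-style values:
    sample factor 1, 75 comparison runs, 100 permutations, 1000 trees)."""

    sample_factor: int = 1
    sample_runs: int = 75
    n_permutations: int = 100
    alpha: float = 0.05
    ntree: int = 1000
    mtry: int | None = None


@dataclass
class GroupSelectionResult:
    method: str
    names: list[str]
    pvalues: np.ndarray
    selected: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            n: {"p_value": float(p), "selected": bool(s)}
            for n, p, s in zip(self.names, self.pvalues, self.selected)
        }


def groups_from_library(
    library: Sequence[SingleSpectrum], grid: np.ndarray, band_extent_k: float = 2.0
) -> list[GroupDefinition]:
    """The 12 spectral groups: all band variables of each single spectrum.

    Characteristic spectra are named S1/S2, background spectra BS3..BS12.
    Variables in overlapping bands of several single spectra belong to
    every such group.
    """
    groups = []
    for s in library:
        mask = np.zeros(grid.shape[0], dtype=bool)
        for m in band_membership(s.bands, grid, band_extent_k):
            mask |= m
        name = f"S{s.id}" if s.characteristic else f"BS{s.id}"
        groups.append(GroupDefinition(name, tuple(np.flatnonzero(mask).tolist())))
    return groups


class _BaseGroupSelector(BaseEstimator):
    def _validate(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        p = X.shape[1]
        for g in self.groups:
            if min(g.indices) < 0 or max(g.indices) >= p:
                raise ValueError(f"group {g.name} has out-of-range indices")
        return X, y


class LeFESelector(_BaseGroupSelector):
    """Competing group test: group importances vs. sampled outside ones.

    Per group and per run, ``sample_factor * |group|`` non-member
    variables are sampled without replacement, a forest is fitted on
    member plus sampled variables, and a one-sided Wilcoxon rank-sum test
    (members greater) yields one p-value.  The group is selected iff the
    aggregate over the runs (median by default; alternatively the
    fraction of significant runs) beats ``alpha``.
    """

    def __init__(
        self,
        groups: Sequence[GroupDefinition],
        sample_factor: int = 1,
        sample_runs: int = 75,
        ntree: int = 1000,
        mtry: int | None = None,
        alpha: float = 0.05,
        aggregation: str = "median",
        random_state: int = 0,
    ):
        self.groups = list(groups)
        self.sample_factor = sample_factor
        self.sample_runs = sample_runs
        self.ntree = ntree
        self.mtry = mtry
        self.alpha = alpha
        self.aggregation = aggregation
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate(X, y)
        p = X.shape[1]
        pvals = []
        run_pvals = []
        for g in self.groups:
            member = np.asarray(g.indices)
            outside = np.setdiff1d(np.arange(p), member)
            if outside.size == 0:
                raise ValueError(f"group {g.name} spans all variables")
            n_sample = min(self.sample_factor * member.size, outside.size)
            # seeded by group content, so results are order-invariant
            rng = np.random.default_rng(
                np.random.SeedSequence([self.random_state, 17, *g.indices])
            )
            ps = np.empty(self.sample_runs)
            for run in range(self.sample_runs):
                sampled = rng.choice(outside, size=n_sample, replace=False)
                cols = np.concatenate([member, sampled])
                model = fit_forest(
                    X[:, cols], y,
                    ForestParams(ntree=self.ntree, mtry=self.mtry),
                    random_state=int(rng.integers(2**31)),
                )
                imp = permutation_importance(
                    model, seed=int(rng.integers(2**31))
                ).values
                ps[run] = stats.mannwhitneyu(
                    imp[: member.size], imp[member.size:],
                    alternative="greater", use_continuity=True,
                    method="asymptotic",
                ).pvalue
            run_pvals.append(ps)
            if self.aggregation == "median":
                pvals.append(np.median(ps))
            elif self.aggregation == "fraction":
                # decision statistic: 1 - fraction of significant runs;
                # selected iff a majority of runs is significant
                pvals.append(1.0 - np.mean(ps < self.alpha))
            else:
                raise ValueError("aggregation must be 'median' or 'fraction'")
        self.pvalues_ = np.asarray(pvals)
        if self.aggregation == "median":
            self.support_ = self.pvalues_ < self.alpha
        else:
            self.support_ = self.pvalues_ < 0.5
        self.run_pvalues_ = run_pvals
        return self

    def result(self) -> GroupSelectionResult:
        return GroupSelectionResult(
            method="lefe",
            names=[g.name for g in self.groups],
            pvalues=self.pvalues_,
            selected=self.support_,
            diagnostics={"aggregation": self.aggregation,
                         "sample_runs": self.sample_runs},
        )


class PredictionErrorSelector(_BaseGroupSelector):
    """Self-sufficient group test: group-only OOB error vs. permuted-label null.

    Per group the observed OOB error ``e0`` of a forest on the group's
    variables is compared to ``n_permutations`` refits with permuted
    labels: ``p = (1 + #{null <= e0}) / (n_permutations + 1)``; the group
    is selected iff ``p <= alpha``.
    """

    def __init__(
        self,
        groups: Sequence[GroupDefinition],
        ntree: int = 1000,
        mtry: int | None = None,
        n_permutations: int = 100,
        alpha: float = 0.05,
        random_state: int = 0,
    ):
        self.groups = list(groups)
        self.ntree = ntree
        self.mtry = mtry
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate(X, y)
        pvals = np.empty(len(self.groups))
        self.oob_errors_ = np.empty(len(self.groups))
        self.null_errors_ = []
        params = ForestParams(ntree=self.ntree, mtry=self.mtry)
        for g_idx, g in enumerate(self.groups):
            rng = np.random.default_rng(
                np.random.SeedSequence([self.random_state, 23, *g.indices])
            )
            Xg = X[:, np.asarray(g.indices)]
            e0 = fit_forest(
                Xg, y, params, random_state=int(rng.integers(2**31))
            ).oob_error()
            null = np.empty(self.n_permutations)
            for k in range(self.n_permutations):
                y_perm = y[rng.permutation(y.shape[0])]
                null[k] = fit_forest(
                    Xg, y_perm, params, random_state=int(rng.integers(2**31))
                ).oob_error()
            pvals[g_idx] = (1.0 + np.sum(null <= e0)) / (self.n_permutations + 1.0)
            self.oob_errors_[g_idx] = e0
            self.null_errors_.append(null)
        self.pvalues_ = pvals
        self.support_ = pvals <= self.alpha
        return self

    def result(self) -> GroupSelectionResult:
        return GroupSelectionResult(
            method="pe",
            names=[g.name for g in self.groups],
            pvalues=self.pvalues_,
            selected=self.support_,
            diagnostics={"oob_errors": self.oob_errors_,
                         "n_permutations": self.n_permutations},
        )


def select_lefe(
    X, y, groups: Sequence[GroupDefinition],
    params: GroupParams | None = None, random_state: int = 0,
) -> GroupSelectionResult:
    params = params or GroupParams()
    return LeFESelector(
        groups, sample_factor=params.sample_factor, sample_runs=params.sample_runs,
        ntree=params.ntree, mtry=params.mtry, alpha=params.alpha,
        random_state=random_state,
    ).fit(X, y).result()


def select_pe(
    X, y, groups: Sequence[GroupDefinition],
    params: GroupParams | None = None, random_state: int = 0,
) -> GroupSelectionResult:
    params = params or GroupParams()
    return PredictionErrorSelector(
        groups, ntree=params.ntree, mtry=params.mtry,
        n_permutations=params.n_permutations, alpha=params.alpha,
        random_state=random_state,
    ).fit(X, y).result()
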