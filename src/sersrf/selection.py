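"""Forest-based variable selection: Vita, Boruta, minimal depth (MD) and
surrogate minimal depth (SMD), as scikit-learn style selector estimators.

All four selectors implement ``fit(X, y)`` / ``get_support()`` /
``transform(X)`` and are deterministic given ``random_state``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .forest import (
    ForestParams,
    first_appearance_depths,
    find_surrogates,
    fit_forest,
    holdout_importance,
    null_depth_threshold,
    permutation_importance,
)

__all__ = [
    "AnalysisParams",
    "SelectionResult",
    "VitaSelector",
    "BorutaSelector",
    "MinimalDepthSelector",
    "select_vita",
    "select_boruta",
    "select_md",
    "select_smd",
]


@dataclass
class AnalysisParams:
    """Shared configuration of the selection methods.

    Defaults follow the full-scale study parameterization: p-value
    threshold 0 for Vita, Boruta confidence 0.01 with at most 100 runs,
    ``s = floor(0.05 p)`` surrogates, threshold factor ``t = 1`` and
    10000 trees.  ``ntree`` is the knob to scale runs down.
    """

    p_threshold: float = 0.0
    boruta_confidence: float = 0.01
    boruta_max_runs: int = 100
    s: int | None = None
    t: float = 1.0
    ntree: int = 10000
    mtry: int | None = None
    nodesize: int = 1

    def forest_params(self) -> ForestParams:
        return ForestParams(ntree=self.ntree, mtry=self.mtry, nodesize=self.nodesize)


@dataclass
class SelectionResult:
    """Outcome of one selection method on one dataset."""

    method: str
    scores: np.ndarray  # importance, p-value or depth per variable
    threshold: float
    selected: np.ndarray  # boolean mask, length p
    diagnostics: dict = field(default_factory=dict)

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.selected)


class _BaseForestSelector(SelectorMixin, BaseEstimator):
    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def _validate(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = X.shape[1]
        return X, y


class VitaSelector(_BaseForestSelector):
    """Vita: p-values from a null built out of non-positive importances.

    Hold-out permutation importance is computed (two stratified halves,
    each forest evaluated on the opposite half); the observed non-positive
    scores, mirrored around zero, estimate the null distribution of
    unimportant variables.  A variable's p-value is the fraction of the
    null sample greater than or equal to its importance; selection
    requires ``p-value <= p_threshold`` (at the default threshold 0 an
    importance must strictly exceed every null value).
    """

    def __init__(
        self,
        ntree: int = 10000,
        mtry: int | None = None,
        p_threshold: float = 0.0,
        importance: str = "holdout",
        random_state: int = 0,
    ):
        self.ntree = ntree
        self.mtry = mtry
        self.p_threshold = p_threshold
        self.importance = importance
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate(X, y)
        params = ForestParams(ntree=self.ntree, mtry=self.mtry)
        if self.importance == "holdout":
            imp = holdout_importance(X, y, params, random_state=self.random_state)
        elif self.importance == "oob":
            model = fit_forest(X, y, params, random_state=self.random_state)
            imp = permutation_importance(model, seed=self.random_state)
        else:
            raise ValueError("importance must be 'holdout' or 'oob'")
        values = imp.values
        nonpos = values[values <= 0]
        if nonpos.size == 0:
            raise RuntimeError(
                "Vita found no non-positive importance scores; the null "
                "distribution cannot be estimated (poor performance is "
                "expected when few non-positive importance scores are "
                "observed)"
            )
        null = np.sort(np.concatenate([nonpos, -nonpos]))
        # p-value: fraction of the null sample >= the observed importance
        counts_ge = null.size - np.searchsorted(null, values, side="left")
        pvalues = counts_ge / null.size
        self.importances_ = values
        self.pvalues_ = pvalues
        self.null_size_ = null.size
        self.support_ = pvalues <= self.p_threshold
        return self

    def result(self) -> SelectionResult:
        return SelectionResult(
            method="vita",
            scores=self.pvalues_,
            threshold=self.p_threshold,
            selected=self.support_,
            diagnostics={"null_size": self.null_size_,
                         "importances": self.importances_},
        )


class BorutaSelector(_BaseForestSelector):
    """Boruta: compare real variables to permuted shadow copies.

    Every run extends the surviving design matrix with freshly permuted
    shadow copies of all its variables, fits a forest, and counts a "hit"
    for each undecided variable whose OOB permutation importance exceeds
    the maximum shadow importance of that run.  A two-sided binomial test
    (Bonferroni-corrected over the currently undecided variables) labels
    variables important or unimportant; unimportant variables are removed
    and the loop repeats until every variable is labeled or ``max_runs``
    is reached.  Variables still tentative at termination are not
    selected.
    """

    def __init__(
        self,
        ntree: int = 10000,
        mtry: int | None = None,
        confidence: float = 0.01,
        max_runs: int = 100,
        random_state: int = 0,
    ):
        self.ntree = ntree
        self.mtry = mtry
        self.confidence = confidence
        self.max_runs = max_runs
        self.random_state = random_state

    def fit(self, X, y):
        X, y = self._validate(X, y)
        p = X.shape[1]
        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 91]))
        undecided = np.ones(p, dtype=bool)
        important = np.zeros(p, dtype=bool)
        hits = np.zeros(p, dtype=np.int64)
        runs = 0
        while undecided.any() and runs < self.max_runs:
            runs += 1
            design_idx = np.flatnonzero(undecided | important)
            Xd = X[:, design_idx]
            shadows = np.empty_like(Xd)
            for j in range(Xd.shape[1]):
                shadows[:, j] = Xd[rng.permutation(X.shape[0]), j]
            Xext = np.hstack([Xd, shadows])
            params = ForestParams(ntree=self.ntree, mtry=self.mtry)
            model = fit_forest(
                Xext, y, params, random_state=self.random_state + runs
            )
            imp = permutation_importance(model, seed=self.random_state + runs).values
            real_imp = imp[: Xd.shape[1]]
            max_shadow = imp[Xd.shape[1]:].max()
            hit_local = real_imp > max_shadow
            und_local = undecided[design_idx]
            hits[design_idx[und_local]] += hit_local[und_local]
            # binomial decision step
            n_und = int(undecided.sum())
            alpha = self.confidence / n_und  # Bonferroni over undecided
            und_idx = np.flatnonzero(undecided)
            h = hits[und_idx]
            p_hi = stats.binom.sf(h - 1, runs, 0.5)  # P(X >= h)
            p_lo = stats.binom.cdf(h, runs, 0.5)  # P(X <= h)
            new_imp = und_idx[p_hi < alpha]
            new_unimp = und_idx[(p_lo < alpha) & ~(p_hi < alpha)]
            important[new_imp] = True
            undecided[new_imp] = False
            undecided[new_unimp] = False
        self.support_ = important
        self.hits_ = hits
        self.runs_used_ = runs
        self.decisions_ = np.where(important, 1, np.where(undecided, 0, -1))
        return self

    def result(self) -> SelectionResult:
        return SelectionResult(
            method="boruta",
            scores=self.hits_.astype(float),
            threshold=float(self.confidence),
            selected=self.support_,
            diagnostics={"runs_used": self.runs_used_,
                         "decisions": self.decisions_},
        )


class MinimalDepthSelector(_BaseForestSelector):
    """Minimal depth (MD) and surrogate minimal depth (SMD) selection.

    A variable's score is its mean depth of first appearance over the
    trees (as primary split, or primary-or-surrogate with
    ``surrogates=True``); variables with depth strictly below ``t`` times
    the Monte-Carlo null mean depth (realized topologies, random variable
    assignment) are selected.
    """

    def __init__(
        self,
        surrogates: bool = False,
        s: int | None = None,
        t: float = 1.0,
        ntree: int = 10000,
        mtry: int | None = None,
        n_null_randomizations: int = 20,
        random_state: int = 0,
    ):
        self.surrogates = surrogates
        self.s = s
        self.t = t
        self.ntree = ntree
        self.mtry = mtry
        self.n_null_randomizations = n_null_randomizations
        self.random_state = random_state

    def fit(self, X, y, model=None):
        """Fit the selector; an already fitted ``ForestModel`` on the same
        data may be passed to reuse it (MD and SMD on one forest)."""
        X, y = self._validate(X, y)
        if model is None:
            params = ForestParams(ntree=self.ntree, mtry=self.mtry)
            model = fit_forest(X, y, params, random_state=self.random_state)
        s = self.s
        if self.surrogates:
            if model.surrogates_ is None:
                find_surrogates(model, s=s)
            s = model.surrogate_s_
        self.depths_ = first_appearance_depths(model, include_surrogates=self.surrogates)
        self.threshold_ = null_depth_threshold(
            model,
            t=self.t,
            include_surrogates=self.surrogates,
            s=s,
            n_randomizations=self.n_null_randomizations,
            seed=self.random_state,
        )
        self.support_ = self.depths_ < self.threshold_
        self.model_ = model
        return self

    def result(self) -> SelectionResult:
        return SelectionResult(
            method="smd" if self.surrogates else "md",
            scores=self.depths_,
            threshold=self.threshold_,
            selected=self.support_,
            diagnostics={"t": self.t},
        )


def _scaled(params: AnalysisParams | None) -> AnalysisParams:
    return params or AnalysisParams()


def select_vita(X, y, params: AnalysisParams | None = None, random_state: int = 0) -> SelectionResult:
    params = _scaled(params)
    sel = VitaSelector(
        ntree=params.ntree, mtry=params.mtry,
        p_threshold=params.p_threshold, random_state=random_state,
    ).fit(X, y)
    return sel.result()


def select_boruta(
    X, y, params: AnalysisParams | None = None, random_state: int = 0
) -> SelectionResult:
    params = _scaled(params)
    sel = BorutaSelector(
        ntree=params.ntree, mtry=params.mtry,
        confidence=params.boruta_confidence, max_runs=params.boruta_max_runs,
        random_state=random_state,
    ).fit(X, y)
    return sel.result()


def select_md(X, y, params: AnalysisParams | None = None, random_state: int = 0, model=None) -> SelectionResult:
    params = _scaled(params)
    sel = MinimalDepthSelector(
        surrogates=False, t=params.t, ntree=params.ntree, mtry=params.mtry,
        random_state=random_state,
    ).fit(X, y, model=model)
    return sel.result()


def select_smd(X, y, params: AnalysisParams | None = None, random_state: int = 0, model=None) -> SelectionResult:
    params = _scaled(params)
    sel = MinimalDepthSelector(
        surrogates=True, s=params.s, t=params.t, ntree=params.ntree,
        mtry=params.mtry, random_state=random_state,
    ).fit(X, y, model=model)
    return sel.result()


SELECTION_DISPATCH = {
    "vita": select_vita,
    "boruta": select_boruta,
    "md": select_md,
    "smd": select_smd,
}
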