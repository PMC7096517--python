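"""Forest core: OOB bookkeeping, importance, surrogates, depths, thresholds.

The permutation-importance and surrogate computations are checked against
independent brute-force loop oracles on small fixtures.
"""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from sersrf import (
    ForestModel,
    ForestParams,
    default_mtry,
    default_surrogate_count,
    find_surrogates,
    first_appearance_depths,
    fit_forest,
    holdout_importance,
    null_depth_threshold,
    permutation_importance,
)


def test_default_parameters():
    assert default_mtry(1401) == 228
    assert default_surrogate_count(1401) == 70
    assert ForestParams(mtry=None).resolve_mtry(1401) == 228
    assert ForestParams(mtry=5000).resolve_mtry(1401) == 1401


def test_fit_validation():
    X = np.random.default_rng(0).normal(size=(10, 3))
    with pytest.raises(ValueError, match="both classes"):
        fit_forest(X, np.zeros(10), ForestParams(ntree=5))
    Xbad = X.copy()
    Xbad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_forest(Xbad, np.repeat([0, 1], 5), ForestParams(ntree=5))


def test_oob_bookkeeping_matches_sklearn(small_study):
    """Re-derived bootstrap/OOB indices reproduce sklearn's own OOB score."""
    _, ds = small_study
    model = fit_forest(ds.spectra, ds.labels, ForestParams(ntree=50, mtry=228), random_state=1)
    rf = RandomForestClassifier(
        n_estimators=50, max_features=228, min_samples_leaf=1,
        bootstrap=True, oob_score=True, random_state=1, n_jobs=1,
    ).fit(ds.spectra, ds.labels)
    assert 1.0 - model.oob_error() == pytest.approx(rf.oob_score_, abs=1e-12)


def test_oob_error_extremes():
    rng = np.random.default_rng(4)
    n = 60
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, 4))
    X[:, 1] = y * 10.0  # perfectly separating variable
    model = fit_forest(X, y, ForestParams(ntree=60, mtry=4), random_state=0)
    assert model.oob_error() < 0.05
    Xnull = rng.normal(size=(n, 4))  # labels independent of X
    model = fit_forest(Xnull, y, ForestParams(ntree=60, mtry=4), random_state=0)
    assert 0.3 < model.oob_error() < 0.7


def _oracle_permutation_importance(model, X, y, seed):
    """Loop reimplementation using sklearn predict and the same
    permutation protocol (per tree, per used variable ascending)."""
    imp = np.zeros(X.shape[1])
    for t_idx, (est, t) in enumerate(zip(model.sk_forest.estimators_, model.trees)):
        oob = t.oob_idx
        Xo = X[oob]
        yo = y[oob]
        acc0 = np.mean(est.predict(Xo) == yo)
        used = np.unique(t.feature[t.feature >= 0])
        rng = np.random.default_rng(np.random.SeedSequence([seed, t_idx]))
        for v in used:
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, v] = Xo[perm, v]
            imp[v] += acc0 - np.mean(est.predict(Xp) == yo)
    return imp / model.ntree


def test_permutation_importance_matches_bruteforce_oracle(tiny_forest):
    X, y, model = tiny_forest
    fast = permutation_importance(model, seed=5).values
    slow = _oracle_permutation_importance(model, X, y, seed=5)
    np.testing.assert_allclose(fast, slow, atol=1e-12)
    assert np.argmax(fast) == 2  # the informative variable dominates


def test_null_variable_importance_near_zero(tiny_forest):
    X, y, model = tiny_forest
    imp = permutation_importance(model, seed=0).values
    noise = np.delete(imp, 2)
    assert np.all(np.abs(noise) < 0.2)
    assert imp[2] > np.abs(noise).max()


class TestHoldoutImportance:
    def test_deterministic_and_strong_predictor(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(60, 6))
        y = np.repeat([0, 1], 30)
        X[y == 1, 0] += 3.0
        a = holdout_importance(X, y, ForestParams(ntree=30, mtry=3), random_state=2)
        b = holdout_importance(X, y, ForestParams(ntree=30, mtry=3), random_state=2)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.variant == "holdout"
        assert np.argmax(a.values) == 0 and a.values[0] > 0

    def test_pure_noise_half_nonpositive(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(80, 40))
        y = np.repeat([0, 1], 40)
        imp = holdout_importance(X, y, ForestParams(ntree=50), random_state=0).values
        frac_nonpos = np.mean(imp <= 0)
        assert 0.25 < frac_nonpos < 0.9


def _oracle_node_surrogates(X, rows, f0, t0):
    """Exhaustive adjusted agreement per candidate variable at one node:
    every midpoint threshold, both orientations."""
    left = X[rows, f0] <= t0
    m = rows.size
    nL = left.sum()
    maj = max(nL, m - nL)
    out = {}
    for v in range(X.shape[1]):
        if v == f0:
            continue
        vals = X[rows, v]
        best = maj
        for c in np.unique(vals)[:-1]:
            assign_left = vals <= c
            matches = np.sum(assign_left == left)
            best = max(best, matches, m - matches)
        out[v] = (best - maj) / (m - maj) if m > maj else 0.0
    return out


def test_surrogates_match_exhaustive_enumeration(tiny_forest):
    X, y, model = tiny_forest
    find_surrogates(model, s=4)
    model.ensure_node_samples()
    checked = 0
    for t, (start, samples), (sv, sa) in zip(
        model.trees, model.node_samples_, model.surrogates_
    ):
        for nd in np.flatnonzero(t.internal):
            rows = samples[start[nd]: start[nd + 1]]
            if rows.size < 2:
                continue
            oracle = _oracle_node_surrogates(model.X, rows, t.feature[nd], t.threshold[nd])
            stored = {int(v): a for v, a in zip(sv[nd], sa[nd]) if v >= 0}
            # every stored surrogate carries its exhaustive adjusted agreement
            for v, a in stored.items():
                assert a == pytest.approx(oracle[v], abs=1e-12)
            # stored set is the top-s of the positive oracle values
            want = sorted((a for a in oracle.values() if a > 0), reverse=True)[:4]
            got = sorted(stored.values(), reverse=True)
            np.testing.assert_allclose(got, want, atol=1e-12)
            checked += 1
    assert checked > 10


def test_perfect_copy_is_perfect_surrogate():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(50, 4))
    y = (X[:, 0] > 0).astype(int)
    X = np.column_stack([X, X[:, 0]])  # variable 4 duplicates variable 0
    model = fit_forest(X, y, ForestParams(ntree=10, mtry=2), random_state=0)
    find_surrogates(model, s=3)
    seen = 0
    for t, (sv, sa) in zip(model.trees, model.surrogates_):
        for nd in np.flatnonzero(t.internal):
            if t.feature[nd] == 0:
                slot = np.flatnonzero(sv[nd] == 4)
                assert slot.size == 1 and sa[nd, slot[0]] == pytest.approx(1.0)
                seen += 1
    assert seen > 0


class TestDepths:
    def test_root_variable_depth_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 3))
        y = (X[:, 1] > 0).astype(int)
        X[:, 1] *= 10  # dominant split variable
        model = fit_forest(X, y, ForestParams(ntree=10, mtry=3), random_state=0)
        depths = first_appearance_depths(model)
        assert depths[1] == 0.0

    def test_oracle_depths_and_surrogate_bound(self, tiny_forest):
        X, y, model = tiny_forest
        find_surrogates(model, s=3)
        md = first_appearance_depths(model, include_surrogates=False)
        smd = first_appearance_depths(model, include_surrogates=True)
        assert np.all(smd <= md + 1e-12)
        # independent loop oracle over the exported trees
        p = X.shape[1]
        expect_md = np.zeros(p)
        expect_smd = np.zeros(p)
        for t, (sv, _) in zip(model.trees, model.surrogates_):
            d_md = np.full(p, t.max_depth + 1, dtype=float)
            d_smd = np.full(p, t.max_depth + 1, dtype=float)
            for nd in range(t.children_left.size):
                if t.children_left[nd] < 0:
                    continue
                d = t.depth[nd]
                v = t.feature[nd]
                d_md[v] = min(d_md[v], d)
                d_smd[v] = min(d_smd[v], d)
                for u in sv[nd]:
                    if u >= 0:
                        d_smd[u] = min(d_smd[u], d)
            expect_md += d_md
            expect_smd += d_smd
        np.testing.assert_allclose(md, expect_md / model.ntree, atol=1e-12)
        np.testing.assert_allclose(smd, expect_smd / model.ntree, atol=1e-12)

    def test_invariant_to_tree_order(self, tiny_forest):
        _, _, model = tiny_forest
        base = first_appearance_depths(model)
        reordered = list(reversed(model.trees))
        orig = model.trees
        try:
            model.trees = reordered
            flipped = first_appearance_depths(model)
        finally:
            model.trees = orig
        np.testing.assert_allclose(base, flipped, atol=1e-12)


class TestNullDepthThreshold:
    def test_zero_factor_and_linearity(self, tiny_forest):
        _, _, model = tiny_forest
        assert null_depth_threshold(model, t=0.0, seed=1) == 0.0
        one = null_depth_threshold(model, t=1.0, seed=1)
        two = null_depth_threshold(model, t=2.0, seed=1)
        assert two == pytest.approx(2 * one, rel=1e-12)
        assert one > 0

    def test_stump_forest_closed_form(self):
        """Stumps: the randomly assigned root variable has depth 0, the
        other p-1 get penalty max_depth+1 = 2, so the null mean depth is
        exactly 2(p-1)/p for every randomization."""
        rng = np.random.default_rng(12)
        p = 5
        X = rng.normal(size=(60, p))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        rf = RandomForestClassifier(
            n_estimators=20, max_depth=1, max_features=3, random_state=0, n_jobs=1
        ).fit(X, y)
        model = ForestModel(rf, X, y)
        thr = null_depth_threshold(model, t=1.0, n_randomizations=5, seed=3)
        assert thr == pytest.approx(2 * (p - 1) / p, abs=1e-12)
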