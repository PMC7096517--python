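"""Numba kernels for per-tree computations.

All kernels operate on the flat array representation of a fitted decision
tree (children_left / children_right / feature / threshold, plus a
per-node predicted class code).  Conventions follow the training library:
a sample goes left iff ``x[feature] <= threshold``; leaves have
``children_left == -1``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_TREE_DEPTH = 512  # path buffer bound; trees on n <= 1e5 stay far below


@njit(cache=True)
def predict_rows(cl, cr, feat, thr, leaf_code, X, rows):
    """Predicted class code for each row index in ``rows``."""
    out = np.empty(rows.shape[0], dtype=np.int8)
    for i in range(rows.shape[0]):
        r = rows[i]
        nd = 0
        while cl[nd] != -1:
            if X[r, feat[nd]] <= thr[nd]:
                nd = cl[nd]
            else:
                nd = cr[nd]
        out[i] = leaf_code[nd]
    return out


@njit(cache=True)
def tree_permutation_importance(
    cl, cr, feat, thr, leaf_code, X, rows, y_codes, used_vars, perms
):
    """Accuracy drop per used variable after permuting its values in ``rows``.

    ``perms[j]`` is a permutation of ``arange(len(rows))``; permuting
    variable ``used_vars[j]`` replaces ``x[rows[i], v]`` by
    ``x[rows[perms[j, i]], v]``.  Only rows whose decision path visits the
    variable are re-traversed; the result is identical to full
    re-prediction with the same permutation.

    Returns (baseline_accuracy, drops) with ``drops[j]`` = baseline
    accuracy minus accuracy after permuting ``used_vars[j]``.
    """
    n_rows = rows.shape[0]
    n_used = used_vars.shape[0]
    correct = np.empty(n_rows, dtype=np.int8)
    # per-row visited features, CSR
    path_feats = np.empty(n_rows * MAX_TREE_DEPTH, dtype=np.int32)
    path_ptr = np.empty(n_rows + 1, dtype=np.int64)
    pos = 0
    n_correct = 0
    for i in range(n_rows):
        path_ptr[i] = pos
        r = rows[i]
        nd = 0
        while cl[nd] != -1:
            path_feats[pos] = feat[nd]
            pos += 1
            if X[r, feat[nd]] <= thr[nd]:
                nd = cl[nd]
            else:
                nd = cr[nd]
        c = 1 if leaf_code[nd] == y_codes[r] else 0
        correct[i] = c
        n_correct += c
    path_ptr[n_rows] = pos
    acc0 = n_correct / n_rows

    # invert: variable -> affected row positions
    var_slot = np.full(X.shape[1], -1, dtype=np.int64)
    for j in range(n_used):
        var_slot[used_vars[j]] = j
    counts = np.zeros(n_used, dtype=np.int64)
    seen_stamp = np.full(X.shape[1], -1, dtype=np.int64)
    for i in range(n_rows):
        for q in range(path_ptr[i], path_ptr[i + 1]):
            v = path_feats[q]
            if seen_stamp[v] != i:  # count each row once per variable
                seen_stamp[v] = i
                counts[var_slot[v]] += 1
    starts = np.zeros(n_used + 1, dtype=np.int64)
    for j in range(n_used):
        starts[j + 1] = starts[j] + counts[j]
    affected = np.empty(starts[n_used], dtype=np.int64)
    fill = starts[:-1].copy()
    seen_stamp[:] = -1
    for i in range(n_rows):
        for q in range(path_ptr[i], path_ptr[i + 1]):
            v = path_feats[q]
            if seen_stamp[v] != i:
                seen_stamp[v] = i
                j = var_slot[v]
                affected[fill[j]] = i
                fill[j] += 1

    drops = np.empty(n_used, dtype=np.float64)
    for j in range(n_used):
        v = used_vars[j]
        delta = 0
        for q in range(starts[j], starts[j + 1]):
            i = affected[q]
            r = rows[i]
            xv = X[rows[perms[j, i]], v]
            nd = 0
            while cl[nd] != -1:
                f = feat[nd]
                val = xv if f == v else X[r, f]
                if val <= thr[nd]:
                    nd = cl[nd]
                else:
                    nd = cr[nd]
            c = 1 if leaf_code[nd] == y_codes[r] else 0
            delta += correct[i] - c
        drops[j] = delta / n_rows
    return acc0, drops


@njit(cache=True)
def build_node_samples(cl, cr, feat, thr, X, boot_idx):
    """CSR assignment of the bootstrap multiset to every tree node."""
    n_nodes = cl.shape[0]
    counts = np.zeros(n_nodes, dtype=np.int64)
    for i in range(boot_idx.shape[0]):
        r = boot_idx[i]
        nd = 0
        counts[nd] += 1
        while cl[nd] != -1:
            if X[r, feat[nd]] <= thr[nd]:
                nd = cl[nd]
            else:
                nd = cr[nd]
            counts[nd] += 1
    start = np.zeros(n_nodes + 1, dtype=np.int64)
    for nd in range(n_nodes):
        start[nd + 1] = start[nd] + counts[nd]
    samples = np.empty(start[n_nodes], dtype=np.int64)
    fill = start[:-1].copy()
    for i in range(boot_idx.shape[0]):
        r = boot_idx[i]
        nd = 0
        samples[fill[nd]] = r
        fill[nd] += 1
        while cl[nd] != -1:
            if X[r, feat[nd]] <= thr[nd]:
                nd = cl[nd]
            else:
                nd = cr[nd]
            samples[fill[nd]] = r
            fill[nd] += 1
    return start, samples


@njit(cache=True)
def best_split_agreement(vals, isleft, nL):
    """Maximal agreement with a binary partition over all threshold cuts.

    ``vals``: candidate variable values for the node samples; ``isleft``:
    the primary split's assignment; ``nL`` its left count.  Cuts are placed
    between consecutive distinct sorted values; both split orientations
    are considered.  Returns the best number of matching samples.
    """
    m = vals.shape[0]
    nR = m - nL
    order = np.argsort(vals)
    best = nL if nL > nR else nR  # majority rule (degenerate cut)
    plc = 0  # primary-left count among the first i+1 sorted samples
    for i in range(m - 1):
        if isleft[order[i]]:
            plc += 1
        if vals[order[i + 1]] > vals[order[i]]:
            k = i + 1  # samples sent left by this cut
            matches = plc + (nR - (k - plc))
            rev = m - matches
            if rev > matches:
                matches = rev
            if matches > best:
                best = matches
    return best


@njit(cache=True)
def tree_surrogates(
    cl, cr, feat, thr, X, node_start, node_samples, candidates, node_mask, s
):
    """Top-``s`` surrogate variables (by adjusted agreement) per node.

    Only nodes with ``node_mask`` true and >= 2 samples are searched, and
    only variables in ``candidates`` are considered.  Adjusted agreement
    is (matches - majority) / (n - majority); non-positive values
    disqualify a surrogate.  Returns (surr_var, surr_adj) with -1 / 0
    padding, surrogates sorted by descending adjusted agreement.
    """
    n_nodes = cl.shape[0]
    n_cand = candidates.shape[0]
    surr_var = np.full((n_nodes, s), -1, dtype=np.int32)
    surr_adj = np.zeros((n_nodes, s), dtype=np.float64)
    max_m = 0
    for nd in range(n_nodes):
        m = node_start[nd + 1] - node_start[nd]
        if m > max_m:
            max_m = m
    vals = np.empty(max_m, dtype=np.float64)
    isleft = np.empty(max_m, dtype=np.bool_)
    adj_buf = np.empty(n_cand, dtype=np.float64)
    for nd in range(n_nodes):
        if cl[nd] == -1 or not node_mask[nd]:
            continue
        a = node_start[nd]
        m = node_start[nd + 1] - a
        if m < 2:
            continue
        f0 = feat[nd]
        t0 = thr[nd]
        nL = 0
        for q in range(m):
            r = node_samples[a + q]
            left = X[r, f0] <= t0
            isleft[q] = left
            if left:
                nL += 1
        maj = nL if nL > m - nL else m - nL
        if maj == m:
            continue
        for ci in range(n_cand):
            v = candidates[ci]
            if v == f0:
                adj_buf[ci] = -1.0
                continue
            for q in range(m):
                vals[q] = X[node_samples[a + q], v]
            best = best_split_agreement(vals[:m], isleft[:m], nL)
            adj_buf[ci] = (best - maj) / (m - maj)
        order = np.argsort(-adj_buf)
        top = s if s < n_cand else n_cand
        for rnk in range(top):
            ci = order[rnk]
            if adj_buf[ci] <= 0.0:
                break
            surr_var[nd, rnk] = candidates[ci]
            surr_adj[nd, rnk] = adj_buf[ci]
    return surr_var, surr_adj


@njit(cache=True)
def null_depth_mean(
    internal_depth, tree_ptr, tree_penalty, p, s, include_surrogates, n_rand, seed
):
    """Mean first-appearance depth when node variables are assigned at random.

    The realized tree topologies are kept: ``internal_depth`` concatenates
    the depths of all internal nodes tree by tree (``tree_ptr`` CSR), and
    ``tree_penalty[t]`` is the depth assigned to variables absent from
    tree ``t`` (max depth + 1).  Each randomization assigns every internal
    node a primary variable uniform on [0, p) plus, optionally, ``s``
    distinct further variables (surrogates); the mean depth over all ``p``
    variables and all trees is returned, averaged over ``n_rand``
    randomizations.
    """
    np.random.seed(seed)
    n_trees = tree_ptr.shape[0] - 1
    depth_arr = np.empty(p, dtype=np.float64)
    stamp = np.full(p, -1, dtype=np.int64)
    stamp_ctr = 0
    total = 0.0
    for it in range(n_rand):
        tree_acc = 0.0
        for t in range(n_trees):
            pen = tree_penalty[t]
            for j in range(p):
                depth_arr[j] = pen
            for q in range(tree_ptr[t], tree_ptr[t + 1]):
                d = internal_depth[q]
                v = np.random.randint(0, p)
                if d < depth_arr[v]:
                    depth_arr[v] = d
                if include_surrogates:
                    stamp_ctr += 1
                    stamp[v] = stamp_ctr
                    drawn = 0
                    while drawn < s:
                        u = np.random.randint(0, p)
                        if stamp[u] == stamp_ctr:
                            continue
                        stamp[u] = stamp_ctr
                        drawn += 1
                        if d < depth_arr[u]:
                            depth_arr[u] = d
            sacc = 0.0
            for j in range(p):
                sacc += depth_arr[j]
            tree_acc += sacc / p
        total += tree_acc / n_trees
    return total / n_rand
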