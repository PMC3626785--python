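"""Numba kernels for regression-tree growth, prediction and permutation importance.

Trees are stored in flat parallel arrays (one row per node):

  feature[i]   split variable index for internal nodes, -1 for leaves
  threshold[i] split threshold ("x <= threshold goes left")
  left[i], right[i]  child node ids (-1 for leaves)
  value[i]     mean of training y routed to the node (leaf prediction)
  n_obs[i]     number of training observations in the node
  deviance[i]  sum of squared deviations of training y within the node

A forest keeps one such block per tree in 2-D arrays of shape
(n_trees, capacity) with capacity = 2 * n_inbag + 1 (a binary tree with
every leaf holding >= 1 observation has at most 2n - 1 nodes).

Randomness: the per-node candidate-variable draw uses numba's internal
legacy PRNG, seeded once per tree with an externally supplied 31-bit seed,
so tree growth is deterministic given (data, inbag, seed).  Permutation
importance likewise takes one seed per tree.
"""

import numpy as np
from numba import njit

LEAF = -1


@njit(cache=True)
def _draw_vars(p, m):
    """Draw m variable indices from 0..p-1 without replacement, sorted ascending.

    Ascending order makes the lowest-column-index tie-break deterministic.
    """
    idx = np.arange(p)
    for i in range(m):
        j = i + np.random.randint(p - i)
        tmp = idx[i]
        idx[i] = idx[j]
        idx[j] = tmp
    return np.sort(idx[:m])


@njit(cache=True)
def grow_tree(X, y, sample_idx, mtry, min_node_size, seed,
              feature, threshold, left, right, value, n_obs, deviance):
    """Grow one regression tree in place; returns the number of nodes used.

    A node is split only if it has >= min_node_size observations, its y
    values are not all equal, and the best candidate split strictly reduces
    the deviance.  Split thresholds sit at midpoints between consecutive
    distinct values; ties in deviance reduction are broken by lowest
    variable index, then smallest threshold.
    """
    np.random.seed(seed)
    n = sample_idx.shape[0]
    idx = sample_idx.copy()
    cap = feature.shape[0]
    stack_node = np.empty(cap, np.int64)
    stack_lo = np.empty(cap, np.int64)
    stack_hi = np.empty(cap, np.int64)
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    top = 1
    node_count = 1
    while top > 0:
        top -= 1
        nid = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        m = hi - lo
        s = 0.0
        for i in range(lo, hi):
            s += y[idx[i]]
        mean = s / m
        sse = 0.0
        ymin = y[idx[lo]]
        ymax = ymin
        for i in range(lo, hi):
            v = y[idx[i]]
            d = v - mean
            sse += d * d
            if v < ymin:
                ymin = v
            if v > ymax:
                ymax = v
        feature[nid] = LEAF
        threshold[nid] = 0.0
        left[nid] = LEAF
        right[nid] = LEAF
        value[nid] = mean
        n_obs[nid] = m
        deviance[nid] = sse
        if m < min_node_size or ymin == ymax:
            continue
        cand = _draw_vars(X.shape[1], mtry)
        best_var = -1
        best_thr = 0.0
        best_red = 0.0
        vals = np.empty(m)
        sy = np.empty(m)
        for c in range(cand.shape[0]):
            j = cand[c]
            for i in range(m):
                vals[i] = X[idx[lo + i], j]
            order = np.argsort(vals)
            total = 0.0
            for i in range(m):
                sy[i] = y[idx[lo + order[i]]]
                total += sy[i]
            cs = 0.0
            css = 0.0
            total_ss = 0.0
            for i in range(m):
                total_ss += sy[i] * sy[i]
            for k in range(1, m):
                cs += sy[k - 1]
                css += sy[k - 1] * sy[k - 1]
                if vals[order[k - 1]] < vals[order[k]]:
                    nl = k
                    nr = m - k
                    sl = css - cs * cs / nl
                    if sl < 0.0:
                        sl = 0.0
                    rs = total - cs
                    sr = (total_ss - css) - rs * rs / nr
                    if sr < 0.0:
                        sr = 0.0
                    red = sse - sl - sr
                    if red > best_red:
                        best_red = red
                        best_var = j
                        best_thr = 0.5 * (vals[order[k - 1]] + vals[order[k]])
        if best_var < 0:
            continue
        # stable in-place partition via temp buffer
        tmp = np.empty(m, np.int64)
        nl = 0
        for i in range(m):
            if X[idx[lo + i], best_var] <= best_thr:
                tmp[nl] = idx[lo + i]
                nl += 1
        nr = nl
        for i in range(m):
            if X[idx[lo + i], best_var] > best_thr:
                tmp[nr] = idx[lo + i]
                nr += 1
        for i in range(m):
            idx[lo + i] = tmp[i]
        lid = node_count
        rid = node_count + 1
        node_count += 2
        feature[nid] = best_var
        threshold[nid] = best_thr
        left[nid] = lid
        right[nid] = rid
        # push right first so the left child is processed next (depth-first,
        # left-to-right); ordering only fixes the RNG stream, deterministically
        stack_node[top] = rid
        stack_lo[top] = lo + nl
        stack_hi[top] = hi
        top += 1
        stack_node[top] = lid
        stack_lo[top] = lo
        stack_hi[top] = lo + nl
        top += 1
    return node_count


@njit(cache=True)
def predict_rows(feature, threshold, left, right, value, X, out):
    """Route every row of X through one tree; write leaf means into out."""
    for r in range(X.shape[0]):
        nid = 0
        while feature[nid] != LEAF:
            if X[r, feature[nid]] <= threshold[nid]:
                nid = left[nid]
            else:
                nid = right[nid]
        out[r] = value[nid]


@njit(cache=True)
def grow_forest(X, y, inbag, tree_seeds, mtry, min_node_size):
    """Grow all trees of a forest; returns the array block and node counts."""
    n_trees = inbag.shape[0]
    n_inbag = inbag.shape[1]
    cap = 2 * n_inbag + 1
    feature = np.full((n_trees, cap), LEAF, np.int64)
    threshold = np.zeros((n_trees, cap))
    left = np.full((n_trees, cap), LEAF, np.int64)
    right = np.full((n_trees, cap), LEAF, np.int64)
    value = np.zeros((n_trees, cap))
    n_obs = np.zeros((n_trees, cap), np.int64)
    deviance = np.zeros((n_trees, cap))
    node_counts = np.empty(n_trees, np.int64)
    for k in range(n_trees):
        node_counts[k] = grow_tree(
            X, y, inbag[k], mtry, min_node_size, tree_seeds[k],
            feature[k], threshold[k], left[k], right[k],
            value[k], n_obs[k], deviance[k])
    return feature, threshold, left, right, value, n_obs, deviance, node_counts


@njit(cache=True)
def oob_masks(inbag, n_rows):
    """Boolean (n_trees, n_rows) mask: True where a row is OOB for a tree."""
    n_trees = inbag.shape[0]
    mask = np.ones((n_trees, n_rows), np.bool_)
    for k in range(n_trees):
        for i in range(inbag.shape[1]):
            mask[k, inbag[k, i]] = False
    return mask


@njit(cache=True)
def forest_predict(feature, threshold, left, right, value, X):
    """Unweighted mean of all trees' predictions for every row of X."""
    n_trees = feature.shape[0]
    n = X.shape[0]
    out = np.zeros(n)
    buf = np.empty(n)
    for k in range(n_trees):
        predict_rows(feature[k], threshold[k], left[k], right[k], value[k],
                     X, buf)
        for r in range(n):
            out[r] += buf[r]
    return out / n_trees


@njit(cache=True)
def oob_stats(feature, threshold, left, right, value, oob, X, y):
    """Per-tree OOB MSE and row-wise OOB-aggregated prediction sums.

    Returns (per_tree_mse, pred_sum, pred_cnt); per_tree_mse is NaN for
    trees with an empty OOB sample.
    """
    n_trees = feature.shape[0]
    n = X.shape[0]
    per_tree_mse = np.full(n_trees, np.nan)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n, np.int64)
    for k in range(n_trees):
        sse = 0.0
        cnt = 0
        for r in range(n):
            if not oob[k, r]:
                continue
            nid = 0
            while feature[k, nid] != LEAF:
                if X[r, feature[k, nid]] <= threshold[k, nid]:
                    nid = left[k, nid]
                else:
                    nid = right[k, nid]
            pred = value[k, nid]
            d = pred - y[r]
            sse += d * d
            pred_sum[r] += pred
            pred_cnt[r] += 1
            cnt += 1
        if cnt > 0:
            per_tree_mse[k] = sse / cnt
    return per_tree_mse, pred_sum, pred_cnt


@njit(cache=True)
def permutation_vi(feature, threshold, left, right, value, oob, X, y,
                   perm_seeds, relative, identity):
    """Per-(tree, variable) permutation importance over each tree's OOB rows.

    For each tree the OOB rows are extracted once; each variable's OOB
    column is permuted (one fresh permutation per (tree, variable) from the
    tree's seeded stream), the tree re-predicts, and the decrease is
    (MSE_perm - MSE_oob) / MSE_oob in relative mode or the raw difference
    otherwise.  NaN marks trees with empty OOB, or zero OOB MSE in relative
    mode.  With identity=True the permutation is the identity (test hook).
    """
    n_trees = feature.shape[0]
    n = X.shape[0]
    p = X.shape[1]
    d = np.full((n_trees, p), np.nan)
    for k in range(n_trees):
        n_oob = 0
        for r in range(n):
            if oob[k, r]:
                n_oob += 1
        if n_oob == 0:
            continue
        Xo = np.empty((n_oob, p))
        yo = np.empty(n_oob)
        i = 0
        for r in range(n):
            if oob[k, r]:
                for j in range(p):
                    Xo[i, j] = X[r, j]
                yo[i] = y[r]
                i += 1
        preds = np.empty(n_oob)
        predict_rows(feature[k], threshold[k], left[k], right[k], value[k],
                     Xo, preds)
        mse0 = 0.0
        for i in range(n_oob):
            e = preds[i] - yo[i]
            mse0 += e * e
        mse0 /= n_oob
        np.random.seed(perm_seeds[k])
        saved = np.empty(n_oob)
        for j in range(p):
            perm = np.random.permutation(n_oob)
            if identity:
                for i in range(n_oob):
                    perm[i] = i
            for i in range(n_oob):
                saved[i] = Xo[i, j]
            for i in range(n_oob):
                Xo[i, j] = saved[perm[i]]
            predict_rows(feature[k], threshold[k], left[k], right[k],
                         value[k], Xo, preds)
            msep = 0.0
            for i in range(n_oob):
                e = preds[i] - yo[i]
                msep += e * e
            msep /= n_oob
            for i in range(n_oob):
                Xo[i, j] = saved[i]
            if relative:
                if mse0 > 0.0:
                    d[k, j] = (msep - mse0) / mse0
            else:
                d[k, j] = msep - mse0
    return d
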