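"""Regression trees grown by exhaustive deviance-minimizing binary splits.

A node is recursively split as long as it holds at least ``min_node_size``
observations, its outcome values are not constant, and some candidate split
strictly reduces the within-node deviance (sum of squared deviations).
Split thresholds are placed at midpoints between consecutive distinct
predictor values; routing is "x <= threshold goes left".  Each leaf predicts
the mean outcome of the training observations routed to it.

Cost-complexity (weakest-link) pruning is provided for standalone use;
trees grown inside forests are never pruned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ParameterError, PredictionError

__all__ = ["RegressionTree", "best_split", "grow_tree", "predict_tree",
           "prune_tree", "cv_select_alpha"]


@dataclass
class RegressionTree:
    """Flat-array binary regression tree (see ``_kernels`` for the layout)."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_obs: np.ndarray
    deviance: np.ndarray
    min_node_size: int = 5
    vars_per_node: int | str = "all"
    predictor_names: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def n_leaves(self) -> int:
        return int(np.sum(self.feature == _kernels.LEAF))

    def leaf_deviance_total(self) -> float:
        return float(self.deviance[self.feature == _kernels.LEAF].sum())

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict a batch of rows (n, p)."""
        X = np.ascontiguousarray(X, dtype=np.float64)
        if np.isnan(X).any():
            raise PredictionError("prediction input contains missing values")
        out = np.empty(X.shape[0])
        _kernels.predict_rows(self.feature, self.threshold, self.left,
                              self.right, self.value, X, out)
        return out

    def to_dict(self) -> dict:
        return {
            "min_node_size": self.min_node_size,
            "vars_per_node": self.vars_per_node,
            "predictor_names": self.predictor_names,
            "nodes": [
                {
                    "feature": int(self.feature[i]),
                    "threshold": float(self.threshold[i]),
                    "left": int(self.left[i]),
                    "right": int(self.right[i]),
                    "value": float(self.value[i]),
                    "n_obs": int(self.n_obs[i]),
                    "deviance": float(self.deviance[i]),
                }
                for i in range(self.n_nodes)
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        nodes = d["nodes"]
        return cls(
            feature=np.array([n["feature"] for n in nodes], np.int64),
            threshold=np.array([n["threshold"] for n in nodes], float),
            left=np.array([n["left"] for n in nodes], np.int64),
            right=np.array([n["right"] for n in nodes], np.int64),
            value=np.array([n["value"] for n in nodes], float),
            n_obs=np.array([n["n_obs"] for n in nodes], np.int64),
            deviance=np.array([n["deviance"] for n in nodes], float),
            min_node_size=d["min_node_size"],
            vars_per_node=d["vars_per_node"],
            predictor_names=d.get("predictor_names"),
        )

    @classmethod
    def from_json(cls, s: str) -> "RegressionTree":
        return cls.from_dict(json.loads(s))


def best_split(X, y, candidate_vars=None):
    """Exhaustive search for the deviance-minimizing binary split.

    Evaluates every (variable, midpoint-between-consecutive-distinct-values)
    split of the candidate variables and returns the one maximizing the
    deviance reduction

        parent SS - (left-child SS + right-child SS).

    Ties are broken by lowest column index, then smallest threshold.
    Returns ``(var, threshold, reduction)`` or ``None`` when no split gives
    a strictly positive reduction (e.g. constant y) or n < 2.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if n < 2:
        return None
    if candidate_vars is None:
        candidate_vars = range(X.shape[1])
    candidate_vars = sorted(int(j) for j in candidate_vars)
    if y.min() == y.max():
        return None
    parent = float(((y - y.mean()) ** 2).sum())
    best = None
    best_red = 0.0
    for j in candidate_vars:
        order = np.argsort(X[:, j], kind="stable")
        sv = X[order, j]
        sy = y[order]
        cs = np.cumsum(sy)
        css = np.cumsum(sy * sy)
        total, total_ss = cs[-1], css[-1]
        for k in range(1, n):
            if sv[k - 1] >= sv[k]:
                continue
            nl, nr = k, n - k
            sl = max(css[k - 1] - cs[k - 1] ** 2 / nl, 0.0)
            rs = total - cs[k - 1]
            sr = max((total_ss - css[k - 1]) - rs * rs / nr, 0.0)
            red = parent - sl - sr
            if red > best_red:
                best_red = red
                best = (j, 0.5 * (sv[k - 1] + sv[k]), red)
    return best


def _as_seed(rng) -> int:
    if rng is None:
        return 0
    if isinstance(rng, (int, np.integer)):
        return int(rng) & 0x7FFFFFFF
    return int(rng.integers(0, 2 ** 31))


def grow_tree(X, y, min_node_size: int = 5, vars_per_node="all",
              rng=None, predictor_names=None) -> RegressionTree:
    """Grow a regression tree by recursive partitioning.

    ``vars_per_node`` draws a fresh uniform subset (without replacement) of
    candidate variables at every node, as used inside random forests;
    ``"all"`` makes growth deterministic regardless of ``rng``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if vars_per_node == "all":
        mtry = p
    else:
        mtry = int(vars_per_node)
        if not 1 <= mtry <= p:
            raise ParameterError(
                f"vars_per_node={mtry} outside [1, p={p}]")
    cap = 2 * n + 1
    feature = np.full(cap, _kernels.LEAF, np.int64)
    threshold = np.zeros(cap)
    left = np.full(cap, _kernels.LEAF, np.int64)
    right = np.full(cap, _kernels.LEAF, np.int64)
    value = np.zeros(cap)
    n_obs = np.zeros(cap, np.int64)
    deviance = np.zeros(cap)
    count = _kernels.grow_tree(X, y, np.arange(n, dtype=np.int64), mtry,
                               int(min_node_size), _as_seed(rng),
                               feature, threshold, left, right, value,
                               n_obs, deviance)
    return RegressionTree(
        feature=feature[:count].copy(), threshold=threshold[:count].copy(),
        left=left[:count].copy(), right=right[:count].copy(),
        value=value[:count].copy(), n_obs=n_obs[:count].copy(),
        deviance=deviance[:count].copy(),
        min_node_size=int(min_node_size), vars_per_node=vars_per_node,
        predictor_names=list(predictor_names) if predictor_names else None)


def predict_tree(tree: RegressionTree, x) -> float:
    """Route a single observation through the tree; return the leaf mean.

    Boundary rule: values exactly at a threshold go left.  Missing values on
    a predictor the tree actually uses raise ``PredictionError`` (there are
    no surrogate splits; designs are complete-case upstream).
    """
    x = np.asarray(x, float)
    nid = 0
    while tree.feature[nid] != _kernels.LEAF:
        v = x[tree.feature[nid]]
        if np.isnan(v):
            raise PredictionError(
                f"missing value for predictor index {int(tree.feature[nid])}")
        nid = tree.left[nid] if v <= tree.threshold[nid] else tree.right[nid]
    return float(tree.value[nid])


def _collapse(tree: RegressionTree, nid: int) -> RegressionTree:
    """Return a copy of the tree with node nid turned into a leaf."""
    keep = np.ones(tree.n_nodes, bool)
    stack = [int(tree.left[nid]), int(tree.right[nid])]
    while stack:
        i = stack.pop()
        if i == _kernels.LEAF:
            continue
        keep[i] = False
        if tree.feature[i] != _kernels.LEAF:
            stack.append(int(tree.left[i]))
            stack.append(int(tree.right[i]))
    remap = np.cumsum(keep) - 1
    new = RegressionTree(
        feature=tree.feature[keep].copy(), threshold=tree.threshold[keep].copy(),
        left=tree.left[keep].copy(), right=tree.right[keep].copy(),
        value=tree.value[keep].copy(), n_obs=tree.n_obs[keep].copy(),
        deviance=tree.deviance[keep].copy(),
        min_node_size=tree.min_node_size, vars_per_node=tree.vars_per_node,
        predictor_names=tree.predictor_names)
    new_nid = int(remap[nid])
    new.feature[new_nid] = _kernels.LEAF
    new.left[new_nid] = _kernels.LEAF
    new.right[new_nid] = _kernels.LEAF
    for i in range(new.n_nodes):
        if new.left[i] != _kernels.LEAF:
            new.left[i] = remap[new.left[i]]
        if new.right[i] != _kernels.LEAF:
            new.right[i] = remap[new.right[i]]
    return new


def _subtree_stats(tree: RegressionTree):
    """(leaf count, summed leaf deviance) of the subtree below every node."""
    n = tree.n_nodes
    leaves = np.zeros(n, np.int64)
    dev = np.zeros(n)
    # children always have larger ids than their parent, so reverse order works
    for i in range(n - 1, -1, -1):
        if tree.feature[i] == _kernels.LEAF:
            leaves[i] = 1
            dev[i] = tree.deviance[i]
        else:
            leaves[i] = leaves[tree.left[i]] + leaves[tree.right[i]]
            dev[i] = dev[tree.left[i]] + dev[tree.right[i]]
    return leaves, dev


def prune_tree(tree: RegressionTree):
    """Weakest-link cost-complexity pruning path.

    Repeatedly collapses the internal node with the smallest link strength

        g(node) = (deviance(node) - summed leaf deviance below) / (leaves - 1)

    and returns the nested sequence ``[(alpha_0 = 0, full tree), (alpha_1,
    subtree_1), ...]`` ending at the root-only tree.  The subtree recorded
    at alpha_k is optimal for all complexity penalties in [alpha_k,
    alpha_{k+1}).  Selecting alpha is the caller's choice; see
    ``cv_select_alpha``.
    """
    path = [(0.0, tree)]
    cur = tree
    while cur.n_leaves > 1:
        leaves, dev = _subtree_stats(cur)
        internal = np.where(cur.feature != _kernels.LEAF)[0]
        g = (cur.deviance[internal] - dev[internal]) / (leaves[internal] - 1)
        alpha = float(g.min())
        # collapse every weakest link at this alpha (ties removed together);
        # node ids shift after each collapse, so re-rank on the current tree
        while True:
            internal = np.where(cur.feature != _kernels.LEAF)[0]
            if len(internal) == 0:
                break
            leaves, dev = _subtree_stats(cur)
            g = (cur.deviance[internal] - dev[internal]) / (
                leaves[internal] - 1)
            i = int(np.argmin(g))
            if g[i] > alpha * (1 + 1e-9) + 1e-12:
                break
            cur = _collapse(cur, int(internal[i]))
        path.append((max(alpha, 0.0), cur))
    return path


def subtree_for_alpha(path, alpha: float) -> RegressionTree:
    """Pick the pruning-path subtree optimal for complexity penalty alpha."""
    best = path[0][1]
    for a, t in path:
        if a <= alpha:
            best = t
        else:
            break
    return best


def cv_select_alpha(X, y, min_node_size: int = 5, n_folds: int = 5,
                    rng=None, one_se: bool = True):
    """K-fold cross-validated complexity selection (optionally 1-SE rule).

    Grows a full tree, takes the geometric midpoints of its pruning-path
    alphas as the candidate grid, scores each by CV MSE of the pruned
    subtree refit per fold, and returns ``(alpha, cv_table)``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    rng = np.random.default_rng(rng)
    full = grow_tree(X, y, min_node_size=min_node_size)
    alphas = [a for a, _ in prune_tree(full)]
    if len(alphas) == 1:
        return 0.0, [(0.0, float(np.var(y)), 0.0)]
    grid = [0.0] + [float(np.sqrt(max(alphas[i], 1e-12) * alphas[i + 1]))
                    for i in range(len(alphas) - 1)]
    n = len(y)
    folds = rng.permutation(n) % n_folds
    errs = np.zeros((len(grid), n_folds))
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        t = grow_tree(X[tr], y[tr], min_node_size=min_node_size)
        p = prune_tree(t)
        for gi, a in enumerate(grid):
            sub = subtree_for_alpha(p, a)
            errs[gi, f] = float(np.mean((sub.predict(X[te]) - y[te]) ** 2))
    mean = errs.mean(axis=1)
    se = errs.std(axis=1, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mean))
    if one_se:
        cutoff = mean[best] + se[best]
        for gi in range(len(grid) - 1, -1, -1):
            if mean[gi] <= cutoff:
                best = gi
                break
    table = list(zip(grid, mean.tolist(), se.tolist()))
    return grid[best], table
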