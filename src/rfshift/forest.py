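"""Random-forest regression: bootstrapped unpruned trees, OOB error, R².

Each tree is grown on a bootstrap sample (n draws with replacement) of the
design, considering a fresh uniform subset of ``mtry`` variables at every
node, and is never pruned.  The forest prediction is the unweighted mean of
the tree predictions.  Rows absent from a tree's bootstrap sample (its
out-of-bag set) serve as that tree's internal test set; the ensemble OOB
error aggregates, for every row, only the trees for which the row is OOB.

One master seed drives independent per-tree substreams (bootstrap draws and
per-node variable subsets), so a fitted forest is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .cart import RegressionTree
from .design import DesignMatrix
from .errors import DegenerateOutcomeError, ParameterError, SchemaError

__all__ = ["ForestParams", "Forest", "fit_forest", "predict_forest",
           "oob_error", "variance_explained", "default_mtry"]


def default_mtry(p: int) -> int:
    """Regression convention: one third of the predictors, at least one."""
    return max(1, p // 3)


@dataclass(frozen=True)
class ForestParams:
    """Forest fitting parameters.

    n_trees: trees per forest (default 500).
    mtry: candidate variables per node; ``None`` means max(1, p // 3).
    min_node_size: a node with fewer observations becomes a leaf (default 5).
    seed: master seed for all randomness in the fit.
    """

    n_trees: int = 500
    mtry: int | None = None
    min_node_size: int = 5
    seed: int = 0

    def resolve_mtry(self, p: int) -> int:
        m = default_mtry(p) if self.mtry is None else int(self.mtry)
        if not 1 <= m <= p:
            raise ParameterError(f"mtry={m} outside [1, p={p}]")
        return m


@dataclass
class Forest:
    """A fitted forest: flat per-tree node blocks plus bootstrap bookkeeping."""

    params: ForestParams
    predictor_names: list[str]
    feature: np.ndarray      # (n_trees, capacity)
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    n_obs: np.ndarray
    deviance: np.ndarray
    node_counts: np.ndarray
    inbag: np.ndarray        # (n_trees, n) sampled row indices
    n_rows: int
    _oob_mask: np.ndarray | None = None

    @property
    def n_trees(self) -> int:
        return self.feature.shape[0]

    @property
    def oob_mask(self) -> np.ndarray:
        """(n_trees, n_rows) boolean: True where a row is OOB for a tree."""
        if self._oob_mask is None:
            self._oob_mask = _kernels.oob_masks(self.inbag, self.n_rows)
        return self._oob_mask

    @property
    def empty_oob_trees(self) -> np.ndarray:
        """Indices of trees whose bootstrap covered every row."""
        return np.where(~self.oob_mask.any(axis=1))[0]

    def tree(self, k: int) -> RegressionTree:
        """Extract tree k as a standalone RegressionTree."""
        c = int(self.node_counts[k])
        return RegressionTree(
            feature=self.feature[k, :c].copy(),
            threshold=self.threshold[k, :c].copy(),
            left=self.left[k, :c].copy(), right=self.right[k, :c].copy(),
            value=self.value[k, :c].copy(), n_obs=self.n_obs[k, :c].copy(),
            deviance=self.deviance[k, :c].copy(),
            min_node_size=self.params.min_node_size,
            vars_per_node=self.params.resolve_mtry(len(self.predictor_names)),
            predictor_names=list(self.predictor_names))

    def summary_dict(self, design: DesignMatrix | None = None) -> dict:
        d = {
            "params": {
                "n_trees": self.params.n_trees,
                "mtry": self.params.resolve_mtry(len(self.predictor_names)),
                "min_node_size": self.params.min_node_size,
                "seed": self.params.seed,
            },
            "predictor_names": list(self.predictor_names),
            "n_rows": self.n_rows,
        }
        if design is not None:
            per_tree, ensemble = oob_error(self, design)
            d["per_tree_oob_mse"] = [None if np.isnan(v) else float(v)
                                     for v in per_tree]
            d["ensemble_oob_mse"] = float(ensemble)
            d["variance_explained"] = float(variance_explained(self, design))
        return d

    def summary_json(self, design: DesignMatrix | None = None) -> str:
        return json.dumps(self.summary_dict(design))


def fit_forest(design: DesignMatrix, params: ForestParams,
               inbag: np.ndarray | None = None) -> Forest:
    """Fit a random forest on a design matrix.

    ``inbag`` injects explicit bootstrap row indices (shape (n_trees, n));
    by default they are drawn with replacement from a seed-derived stream.
    Passing ``np.tile(np.arange(n), (n_trees, 1))`` disables resampling
    (every tree sees the full sample, a degenerate-ensemble test hook).
    Trees whose bootstrap happens to cover all rows are kept but flagged
    (``Forest.empty_oob_trees``).
    """
    n = design.n
    if n < 2:
        raise ParameterError("need at least 2 rows to fit a forest")
    mtry = params.resolve_mtry(design.p)
    ss = np.random.SeedSequence(params.seed)
    boot_ss, tree_ss = ss.spawn(2)
    if inbag is None:
        rng = np.random.default_rng(boot_ss)
        inbag = rng.integers(0, n, size=(params.n_trees, n), dtype=np.int64)
    else:
        inbag = np.ascontiguousarray(inbag, dtype=np.int64)
        if inbag.shape[0] != params.n_trees:
            raise ParameterError("inbag rows must equal n_trees")
    tree_seeds = (tree_ss.generate_state(params.n_trees, np.uint64)
                  & np.uint64(0x7FFFFFFF)).astype(np.int64)
    feature, threshold, left, right, value, n_obs, deviance, counts = (
        _kernels.grow_forest(design.X, design.y, inbag, tree_seeds, mtry,
                             int(params.min_node_size)))
    return Forest(params=params, predictor_names=list(design.predictor_names),
                  feature=feature, threshold=threshold, left=left,
                  right=right, value=value, n_obs=n_obs, deviance=deviance,
                  node_counts=counts, inbag=inbag, n_rows=n)


def _check_columns(forest: Forest, X_new) -> np.ndarray:
    if isinstance(X_new, DesignMatrix):
        if X_new.predictor_names != forest.predictor_names:
            raise SchemaError("prediction columns do not match training design")
        return X_new.X
    X = np.ascontiguousarray(X_new, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(forest.predictor_names):
        raise SchemaError(
            f"expected {len(forest.predictor_names)} columns, got {X.shape[1]}")
    return X


def predict_forest(forest: Forest, X_new) -> np.ndarray:
    """Unweighted mean of all trees' predictions."""
    X = _check_columns(forest, X_new)
    return _kernels.forest_predict(forest.feature, forest.threshold,
                                   forest.left, forest.right, forest.value,
                                   X)


def oob_error(forest: Forest, design: DesignMatrix):
    """OOB performance of a fitted forest on its own training design.

    Returns ``(per_tree_mse, ensemble_oob_mse)``: per-tree MSE on each
    tree's OOB rows (NaN for trees with empty OOB, which are excluded from
    averages), and the MSE of OOB-aggregated predictions, where every row is
    predicted by averaging only the trees for which it is OOB.  Rows that
    were in-bag for every tree are excluded from the ensemble figure.
    """
    per_tree, pred_sum, pred_cnt = _kernels.oob_stats(
        forest.feature, forest.threshold, forest.left, forest.right,
        forest.value, forest.oob_mask, design.X, design.y)
    covered = pred_cnt > 0
    if np.isnan(per_tree).any():
        warnings.warn(f"{int(np.isnan(per_tree).sum())} tree(s) had empty OOB "
                      "samples and are excluded from OOB averages")
    if not covered.any():
        return per_tree, float("nan")
    resid = pred_sum[covered] / pred_cnt[covered] - design.y[covered]
    return per_tree, float(np.mean(resid ** 2))


def variance_explained(forest: Forest, design: DesignMatrix) -> float:
    """1 - OOB MSE / population variance of y (may be negative)."""
    var = float(np.var(design.y))  # population (divide-by-n) variance
    if var == 0.0:
        raise DegenerateOutcomeError("outcome has zero variance")
    _, ensemble = oob_error(forest, design)
    return 1.0 - ensemble / var
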