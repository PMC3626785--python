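"""Permutation variable importance over OOB samples, and its K-run average.

A variable's importance (VI) for one forest is the mean, over trees, of the
relative decrease in the tree's OOB performance when the variable's values
are randomly permuted within the tree's OOB sample:

    d(k, j) = (MSE_perm(k, j) - MSE_oob(k)) / MSE_oob(k)      (relative mode)
    d(k, j) =  MSE_perm(k, j) - MSE_oob(k)                    (raw mode)

One fresh permutation is drawn per (tree, variable); stabilization comes
from the averaged VI (AVI): the mean VI over K independently seeded forest
fits of the same design.  Negative values are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .design import DesignMatrix
from .forest import Forest, ForestParams, fit_forest, variance_explained

__all__ = ["ImportanceResult", "AVIResult", "permutation_vi", "average_vi",
           "aggregate_importance"]


@dataclass
class ImportanceResult:
    """Single-forest permutation importance."""

    vi: dict[str, float]
    per_tree: dict[str, np.ndarray]
    mode: str

    def aggregated(self, column_groups: dict[str, list[str]]) -> dict[str, float]:
        return aggregate_importance(self.vi, column_groups)


@dataclass
class AVIResult:
    """Averaged variable importance over K independent forest runs."""

    avi: dict[str, float]
    sd: dict[str, float]
    K: int
    mode: str = "relative"
    variance_explained_mean: float | None = None

    def aggregated(self, column_groups: dict[str, list[str]]) -> dict[str, float]:
        return aggregate_importance(self.avi, column_groups)


def aggregate_importance(values: dict[str, float],
                         column_groups: dict[str, list[str]]) -> dict[str, float]:
    """Sum encoded-column importances back to their original variables."""
    return {orig: float(sum(values[c] for c in cols))
            for orig, cols in column_groups.items()
            if all(c in values for c in cols)}


def permutation_vi(forest: Forest, design: DesignMatrix, rng=None,
                   mode: str = "relative",
                   identity_permutations: bool = False) -> ImportanceResult:
    """Permutation importance of every design column for one fitted forest.

    ``rng`` (int seed or numpy Generator) drives the per-tree permutation
    streams.  Trees with empty OOB samples — and, in relative mode, trees
    with zero OOB MSE — are excluded from each variable's mean.
    ``identity_permutations`` forces the identity permutation (test hook:
    all importances are exactly zero).
    """
    if mode not in ("relative", "raw"):
        raise ValueError("mode must be 'relative' or 'raw'")
    rng = np.random.default_rng(rng)
    perm_seeds = rng.integers(0, 2 ** 31, size=forest.n_trees,
                              dtype=np.int64)
    d = _kernels.permutation_vi(
        forest.feature, forest.threshold, forest.left, forest.right,
        forest.value, forest.oob_mask, design.X, design.y, perm_seeds,
        mode == "relative", identity_permutations)
    names = forest.predictor_names
    with np.errstate(invalid="ignore"):
        means = np.nanmean(d, axis=0)
    return ImportanceResult(
        vi={names[j]: float(means[j]) for j in range(len(names))},
        per_tree={names[j]: d[:, j].copy() for j in range(len(names))},
        mode=mode)


def _run_seeds(master_seed: int, K: int):
    """K independent (forest seed, permutation seed) pairs, each < 2^31."""
    children = np.random.SeedSequence(master_seed).spawn(K)
    out = []
    for child in children:
        a, b = child.generate_state(2, np.uint64) & np.uint64(0x7FFFFFFF)
        out.append((int(a), int(b)))
    return out


def average_vi(design: DesignMatrix, params: ForestParams, K: int = 300,
               master_seed: int = 0, mode: str = "relative") -> AVIResult:
    """AVI: mean and SD of per-forest VI over K independently seeded runs.

    Also records the mean OOB variance explained over the K forests.
    Deterministic given ``master_seed``; with K = 1 the AVI equals the
    single forest's VI and the SD is zero.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    names = list(design.predictor_names)
    vis = np.empty((K, len(names)))
    ves = np.empty(K)
    for k, (fseed, pseed) in enumerate(_run_seeds(master_seed, K)):
        fparams = ForestParams(n_trees=params.n_trees, mtry=params.mtry,
                               min_node_size=params.min_node_size, seed=fseed)
        forest = fit_forest(design, fparams)
        res = permutation_vi(forest, design, rng=pseed, mode=mode)
        vis[k] = [res.vi[n] for n in names]
        ves[k] = variance_explained(forest, design)
    sd = vis.std(axis=0, ddof=1) if K > 1 else np.zeros(len(names))
    return AVIResult(
        avi={n: float(vis[:, j].mean()) for j, n in enumerate(names)},
        sd={n: float(sd[j]) for j, n in enumerate(names)},
        K=K, mode=mode, variance_explained_mean=float(ves.mean()))
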