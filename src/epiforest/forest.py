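"""From-scratch Random Forest classifier for ordinal genotype predictors.

Breiman bagging with CART trees grown to purity by default: each tree is fit
on a bootstrap sample of size n, at every node ``mtry`` candidate variables
are drawn without replacement and the split maximizing the Gini impurity
decrease over the two ordinal genotype cutpoints is chosen.  The ensemble
reports the out-of-bag (OOB) misclassification rate and four per-variable
importance measures:

raw MDA
    mean over *all* trees of the drop in single-tree OOB accuracy after
    permuting the variable among that tree's OOB individuals (zero for trees
    not using the variable),
scaled (Liaw) MDA
    raw MDA divided by its estimated standard error,
    ``raw / sqrt(s^2 / ntree)`` with ``s^2`` the variance of the per-tree
    drops over all trees,
Meng MDA
    mean of the per-tree drops over only the trees that use the variable,
Gini importance
    bootstrap-weighted total impurity decrease of the variable's splits,
    averaged over trees.

Defaults mirror common GWAS screening practice: ``mtry = round(0.1 p)`` and a
large ``ntree`` (the study design uses 5000; reduced-scale runs use 500).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tree_kernels import (
    grow_tree_kernel,
    perm_importance_tree_kernel,
    predict_tree_kernel,
)
from .gensim import GenotypeMatrix

__all__ = [
    "ForestConfig",
    "Tree",
    "Forest",
    "ImportanceReport",
    "default_mtry",
    "grow_tree",
    "fit_forest",
    "oob_error",
    "permutation_importance",
    "gini_importance",
    "analyze",
]


def default_mtry(p: int) -> int:
    """Study default: 10% of the panel, at least 1."""
    return max(1, round(0.1 * p))


@dataclass(frozen=True)
class ForestConfig:
    ntree: int = 5000
    mtry: int | None = None  # None -> round(0.1 p) at fit time
    seed: int = 0
    min_node_size: int = 1  # 1 = split to purity

    def __post_init__(self):
        if self.ntree < 1:
            raise ValueError("ntree must be at least 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be at least 1")
        if self.min_node_size < 1:
            raise ValueError("min_node_size must be at least 1")

    def resolve_mtry(self, p: int) -> int:
        mtry = default_mtry(p) if self.mtry is None else self.mtry
        if mtry > p:
            raise ValueError(f"mtry={mtry} exceeds panel size p={p}")
        return mtry


@dataclass
class Tree:
    """Flat-array CART tree with its bootstrap bookkeeping."""

    feature: np.ndarray  # int32, -1 for leaves
    cut: np.ndarray  # int8, genotype <= cut goes left
    left: np.ndarray
    right: np.ndarray
    pred: np.ndarray
    gain: np.ndarray  # per-node (node_size/n) * Gini decrease
    bootstrap_indices: np.ndarray
    oob_indices: np.ndarray

    @property
    def used_vars(self) -> np.ndarray:
        return np.unique(self.feature[self.feature >= 0])

    def predict(self, X: np.ndarray, idx: np.ndarray | None = None) -> np.ndarray:
        if idx is None:
            idx = np.arange(X.shape[0])
        return predict_tree_kernel(
            self.feature, self.cut, self.left, self.right, self.pred, X, idx.astype(np.int64)
        )


@dataclass
class Forest:
    trees: list[Tree]
    config: ForestConfig
    n: int
    p: int
    mtry: int

    @property
    def ntree(self) -> int:
        return len(self.trees)


def _as_xy(G, y):
    X = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    X = np.ascontiguousarray(X, dtype=np.int8)
    y = np.ascontiguousarray(np.asarray(y), dtype=np.int8)
    if X.shape[0] != y.size:
        raise ValueError("genotype and phenotype lengths disagree")
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("labels must be binary 0/1")
    return X, y


def grow_tree(G, y, config: ForestConfig, tree_seed: int) -> Tree:
    """Grow one tree on its own seeded bootstrap of size n."""
    X, y = _as_xy(G, y)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two individuals")
    mtry = config.resolve_mtry(p)
    rng = np.random.default_rng(tree_seed)
    bootstrap = rng.integers(0, n, size=n).astype(np.int64)
    inbag_mask = np.zeros(n, dtype=bool)
    inbag_mask[bootstrap] = True
    oob = np.flatnonzero(~inbag_mask).astype(np.int64)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    feature, cut, left, right, pred, gain = grow_tree_kernel(
        X, y, bootstrap.copy(), mtry, config.min_node_size, kernel_seed
    )
    return Tree(feature, cut, left, right, pred, gain, bootstrap, oob)


def fit_forest(G, y, config: ForestConfig) -> Forest:
    """Fit ``ntree`` trees on independent seeded bootstraps; fully deterministic."""
    X, y = _as_xy(G, y)
    n, p = X.shape
    mtry = config.resolve_mtry(p)
    tree_seeds = np.random.SeedSequence(config.seed).generate_state(config.ntree) % (2**31 - 1)
    trees = [grow_tree(X, y, config, int(s)) for s in tree_seeds]
    return Forest(trees=trees, config=config, n=n, p=p, mtry=mtry)


def oob_error(forest: Forest, G, y) -> float:
    """Forest OOB misclassification: majority vote over each sample's OOB trees.

    Vote ties predict class 0 (control); individuals OOB in no tree are
    excluded from the denominator.
    """
    X, y = _as_xy(G, y)
    votes = np.zeros((forest.n, 2), dtype=np.int32)
    for tree in forest.trees:
        preds = tree.predict(X, tree.oob_indices)
        np.add.at(votes, (tree.oob_indices, preds.astype(np.intp)), 1)
    covered = votes.sum(axis=1) > 0
    if not np.any(covered):
        raise ValueError("no individual was out-of-bag in any tree; increase ntree")
    final = (votes[:, 1] > votes[:, 0]).astype(np.int8)
    return float(np.mean(final[covered] != y[covered]))


def permutation_importance(forest: Forest, G, y, seed) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP (raw MDA, scaled MDA, Meng MDA) from one seeded OOB permutation
    of each (tree, used-variable) pair."""
    X, y = _as_xy(G, y)
    p = forest.p
    ntree = forest.ntree
    sum_d = np.zeros(p)
    sumsq_d = np.zeros(p)
    used_count = np.zeros(p, dtype=np.int64)
    perm_seeds = np.random.SeedSequence(seed).generate_state(ntree) % (2**31 - 1)
    for tree, pseed in zip(forest.trees, perm_seeds):
        used = tree.used_vars.astype(np.int64)
        if used.size == 0:
            continue
        perm_importance_tree_kernel(
            tree.feature,
            tree.cut,
            tree.left,
            tree.right,
            tree.pred,
            X,
            y,
            tree.oob_indices,
            used,
            int(pseed),
            sum_d,
            sumsq_d,
            used_count,
        )
    raw = sum_d / ntree
    if ntree > 1:
        s2 = (sumsq_d - ntree * raw**2) / (ntree - 1)
        s2 = np.maximum(s2, 0.0)
    else:
        s2 = np.zeros(p)
    se = np.sqrt(s2 / ntree)
    scaled = np.divide(raw, se, out=np.zeros(p), where=se > 0)
    meng = np.divide(sum_d, used_count, out=np.zeros(p), where=used_count > 0)
    return raw, scaled, meng


def gini_importance(forest: Forest) -> np.ndarray:
    """Per-SNP total bootstrap-weighted impurity decrease, averaged over trees."""
    totals = np.zeros(forest.p)
    for tree in forest.trees:
        split = tree.feature >= 0
        if np.any(split):
            np.add.at(totals, tree.feature[split], tree.gain[split])
    return totals / forest.ntree


@dataclass
class ImportanceReport:
    """Per-SNP importance scores plus the forest-level OOB error."""

    raw_mda: np.ndarray
    scaled_mda: np.ndarray
    meng_mda: np.ndarray
    gini: np.ndarray
    oob_error: float

    def to_frame(self, snp_ids=None):
        import pandas as pd

        p = self.raw_mda.size
        return pd.DataFrame(
            {
                "snp": snp_ids if snp_ids is not None else [f"snp{j}" for j in range(p)],
                "raw_mda": self.raw_mda,
                "scaled_mda": self.scaled_mda,
                "meng_mda": self.meng_mda,
                "gini": self.gini,
            }
        )


def analyze(G, y, config: ForestConfig, importance_seed=None) -> ImportanceReport:
    """Fit a forest and compute OOB error and all four importance measures."""
    forest = fit_forest(G, y, config)
    if importance_seed is None:
        importance_seed = config.seed + 1
    raw, scaled, meng = permutation_importance(forest, G, y, importance_seed)
    return ImportanceReport(
        raw_mda=raw,
        scaled_mda=scaled,
        meng_mda=meng,
        gini=gini_importance(forest),
        oob_error=oob_error(forest, G, y),
    )
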