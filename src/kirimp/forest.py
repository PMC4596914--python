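"""Classification-tree ensembles for categorical targets over binary alleles.

This is the statistical engine of the imputation method: CART-style trees
grown on bootstrap resamples of a reference panel (bagging), with a random
candidate subset of SNPs drawn at every node (attribute bagging / random
subspace).  Because predictors are phased binary alleles, every split is
two-way.  The ensemble predicts by hard per-tree votes, so the reported
probability of a class is exactly the fraction of trees voting for it.

Out-of-bag (OOB) machinery is first-class: each tree records its bootstrap
index multiset, enabling OOB prediction (an internal proxy for
cross-validation) and Breiman-style permutation variable importance, where a
SNP's alleles are permuted within each tree's OOB set and the mean accuracy
drop is normalized by the SD of the per-tree drops.

Defaults follow the published tuning for this problem: 1000 trees, no node
limit, and an attribute-subspace size m of 100 for panels of a few hundred
SNPs (m = 10 for ~12-SNP sets); the classical fallback is floor(sqrt(n_snps)).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ForestParams",
    "Tree",
    "Forest",
    "ImportanceScores",
    "sqrt_m_try",
    "default_m_try",
    "grow_tree",
    "fit_forest",
]

_LEAF = -1

try:  # JIT-compiled tree growth; pure-numpy fallback keeps semantics identical
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap


@_njit(cache=True)
def _grow_nodes(X, y, k, m, max_nodes, boot, rng):  # pragma: no cover - jitted
    """Grow one tree over bootstrap rows ``boot``; returns packed node arrays.

    Splits minimize Gini impurity over ``m`` candidate SNPs drawn without
    replacement per node; ties go to the smallest SNP index, leaf ties to the
    smallest class code.  Node count never exceeds 2*len(boot)-1.
    """
    n_snps = X.shape[1]
    cap = 2 * boot.shape[0] + 1
    feature = np.full(cap, -1, dtype=np.int32)
    children = np.full((cap, 2), -1, dtype=np.int32)
    leaf_class = np.full(cap, -1, dtype=np.int32)
    # rows stored in one arena; each node owns a [start, end) slice
    arena = boot.astype(np.int64).copy()
    stack_node = np.empty(cap, dtype=np.int32)
    stack_lo = np.empty(cap, dtype=np.int64)
    stack_hi = np.empty(cap, dtype=np.int64)
    pool = np.arange(n_snps, dtype=np.int64)
    cand = np.empty(m, dtype=np.int64)
    counts = np.empty(k, dtype=np.int64)
    c1 = np.empty((m, k), dtype=np.int64)
    n_nodes = 1
    top = 0
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = arena.shape[0]
    while top >= 0:
        node = stack_node[top]
        lo = stack_lo[top]
        hi = stack_hi[top]
        top -= 1
        n_i = hi - lo
        counts[:] = 0
        for r in range(lo, hi):
            counts[y[arena[r]]] += 1
        n_classes_here = 0
        for c in range(k):
            if counts[c] > 0:
                n_classes_here += 1
        if n_classes_here <= 1 or n_nodes + 2 > max_nodes:
            best_c = 0
            for c in range(1, k):
                if counts[c] > counts[best_c]:
                    best_c = c
            leaf_class[node] = best_c
            continue
        # draw m candidates without replacement (partial Fisher-Yates), sort
        for t in range(m):
            j = t + rng.integers(0, n_snps - t)
            tmp = pool[t]
            pool[t] = pool[j]
            pool[j] = tmp
            cand[t] = pool[t]
        cand[:m].sort()
        for t in range(n_snps):
            pool[t] = t
        c1[:, :] = 0
        for r in range(lo, hi):
            row = arena[r]
            cls = y[row]
            for t in range(m):
                if X[row, cand[t]] == 1:
                    c1[t, cls] += 1
        # parent impurity (times n_i) minus weighted child impurity
        sq = 0.0
        for c in range(k):
            sq += counts[c] * counts[c]
        parent_imp = n_i - sq / n_i
        best_t = -1
        best_imp = np.inf
        for t in range(m):
            n1 = 0
            for c in range(k):
                n1 += c1[t, c]
            n0 = n_i - n1
            if n0 == 0 or n1 == 0:
                continue
            s0 = 0.0
            s1 = 0.0
            for c in range(k):
                d1 = c1[t, c]
                d0 = counts[c] - d1
                s0 += d0 * d0
                s1 += d1 * d1
            imp = (n0 - s0 / n0) + (n1 - s1 / n1)
            if imp < best_imp - 1e-12:
                best_imp = imp
                best_t = t
        if best_t < 0 or parent_imp - best_imp <= 1e-12:
            best_c = 0
            for c in range(1, k):
                if counts[c] > counts[best_c]:
                    best_c = c
            leaf_class[node] = best_c
            continue
        snp = cand[best_t]
        # in-place partition of the node's arena slice: allele 0 left, 1 right
        i = lo
        j = hi - 1
        while i <= j:
            if X[arena[i], snp] == 0:
                i += 1
            else:
                tmp2 = arena[i]
                arena[i] = arena[j]
                arena[j] = tmp2
                j -= 1
        mid = i
        left = n_nodes
        right = n_nodes + 1
        n_nodes += 2
        feature[node] = snp
        children[node, 0] = left
        children[node, 1] = right
        top += 1
        stack_node[top] = left
        stack_lo[top] = lo
        stack_hi[top] = mid
        top += 1
        stack_node[top] = right
        stack_lo[top] = mid
        stack_hi[top] = hi
    return feature[:n_nodes], children[:n_nodes], leaf_class[:n_nodes]


def sqrt_m_try(n_snps: int) -> int:
    """Classical attribute-subspace fallback: floor(sqrt(n_snps))."""
    return max(1, int(math.floor(math.sqrt(n_snps))))


def default_m_try(n_snps: int) -> int:
    """Tuned subspace size: 100 for panels of >=100 SNPs, 10 for >=10, else all.

    Larger m than the sqrt fallback helps loci whose information sits in a
    handful of SNPs: with small m, many trees would never see those SNPs.
    """
    if n_snps >= 100:
        return 100
    if n_snps >= 10:
        return 10
    return n_snps


@dataclass(frozen=True)
class ForestParams:
    """Ensemble hyperparameters.

    ``m_try=None`` resolves at fit time via :func:`default_m_try`;
    ``max_nodes=None`` means trees grow until pure.
    """

    n_trees: int = 1000
    m_try: int | None = None
    max_nodes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.m_try is not None and self.m_try < 1:
            raise ValueError("m_try must be >= 1")

    def resolve_m_try(self, n_snps: int) -> int:
        m = self.m_try if self.m_try is not None else default_m_try(n_snps)
        if m > n_snps:
            raise ValueError(f"m_try={m} exceeds the {n_snps} available SNPs")
        return m


@dataclass
class Tree:
    """One classification tree in array form plus its bootstrap record.

    ``feature[k]`` is the SNP index split at node ``k`` (or -1 for a leaf),
    ``children[k, a]`` the child node reached with allele ``a``, and
    ``leaf_class[k]`` the predicted class code at leaves.
    """

    feature: np.ndarray      # int32, -1 at leaves
    children: np.ndarray     # int32 (n_nodes, 2)
    leaf_class: np.ndarray   # int32, -1 at internal nodes
    bootstrap: np.ndarray    # int32 bootstrap row indices (the multiset)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def used_features(self) -> np.ndarray:
        f = self.feature
        return np.unique(f[f >= 0])

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Class code for each row of a binary allele matrix."""
        node = np.zeros(X.shape[0], dtype=np.int32)
        active = self.feature[node] >= 0
        while active.any():
            idx = np.where(active)[0]
            nd = node[idx]
            alle = X[idx, self.feature[nd]]
            node[idx] = self.children[nd, alle]
            active = self.feature[node] >= 0
        return self.leaf_class[node]


_NO_NODE_LIMIT = np.iinfo(np.int64).max


def _build_tree(X, y_codes, n_classes, m_try, max_nodes, rng,
                bootstrap: np.ndarray) -> Tree:
    limit = _NO_NODE_LIMIT if max_nodes is None else int(max_nodes)
    feature, children, leaf_class = _grow_nodes(
        X, y_codes, n_classes, m_try, limit,
        np.asarray(bootstrap, dtype=np.int64), rng,
    )
    return Tree(
        feature=np.asarray(feature, dtype=np.int32),
        children=np.asarray(children, dtype=np.int32),
        leaf_class=np.asarray(leaf_class, dtype=np.int32),
        bootstrap=np.asarray(bootstrap, dtype=np.int32),
    )


def _validate_X(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D haplotype x SNP matrix")
    if (X < 0).any():
        raise ValueError(
            "X contains missing alleles; impute or drop them upstream before fitting"
        )
    if not np.isin(X, (0, 1)).all():
        raise ValueError("X entries must be binary alleles 0/1")
    return X.astype(np.int8)


def grow_tree(
    X: np.ndarray,
    y: Sequence,
    params: ForestParams,
    rng: np.random.Generator,
    bootstrap: np.ndarray | None = None,
) -> tuple[Tree, np.ndarray]:
    """Grow one CART tree on (a bootstrap of) the training data.

    Returns the tree and the array of class labels indexing its codes.
    A single-class target yields a single-leaf tree.
    """
    X = _validate_X(X)
    classes, y_codes = np.unique(np.asarray(y), return_inverse=True)
    n = X.shape[0]
    if bootstrap is None:
        bootstrap = np.arange(n, dtype=np.int32)
    m = params.resolve_m_try(X.shape[1])
    tree = _build_tree(X, y_codes.astype(np.int64), len(classes), m,
                       params.max_nodes, rng, bootstrap)
    return tree, classes


@dataclass
class ImportanceScores:
    """Permutation variable importance: mean OOB accuracy drop / SD of drops."""

    snp_index: np.ndarray
    score: np.ndarray
    mean_drop: np.ndarray
    sd_drop: np.ndarray


class Forest:
    """A fitted ensemble over one categorical target (one KIR locus)."""

    def __init__(self, trees: list[Tree], classes: np.ndarray, n_snps: int,
                 params: ForestParams, snp_ids: list[str] | None = None):
        self.trees = trees
        self.classes = classes
        self.n_snps = n_snps
        self.params = params
        self.snp_ids = snp_ids

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    # -- prediction ---------------------------------------------------------

    def _check_X(self, X: np.ndarray, snp_ids: list[str] | None = None) -> np.ndarray:
        X = _validate_X(X)
        if snp_ids is not None and self.snp_ids is not None:
            missing = [s for s in self.snp_ids if s not in set(snp_ids)]
            if missing:
                raise ValueError(f"input lacks model SNPs: {missing}")
            order = {s: i for i, s in enumerate(snp_ids)}
            X = X[:, [order[s] for s in self.snp_ids]]
        elif X.shape[1] != self.n_snps:
            raise ValueError(
                f"input has {X.shape[1]} SNPs but the model was trained on "
                f"{self.n_snps}"
            )
        return X

    def vote_counts(self, X: np.ndarray) -> np.ndarray:
        X = self._check_X(X)
        votes = np.zeros((X.shape[0], self.n_classes), dtype=np.int64)
        rows = np.arange(X.shape[0])
        for tree in self.trees:
            votes[rows, tree.predict_codes(X)] += 1
        return votes

    def predict_proba(self, X: np.ndarray, snp_ids: list[str] | None = None) -> np.ndarray:
        """Per-row class distribution: fraction of trees voting each class."""
        X = self._check_X(X, snp_ids)
        votes = np.zeros((X.shape[0], self.n_classes), dtype=np.int64)
        rows = np.arange(X.shape[0])
        for tree in self.trees:
            votes[rows, tree.predict_codes(X)] += 1
        return votes / len(self.trees)

    def predict(self, X: np.ndarray, snp_ids: list[str] | None = None) -> np.ndarray:
        proba = self.predict_proba(X, snp_ids)
        return self.classes[np.argmax(proba, axis=1)]

    # -- out-of-bag ---------------------------------------------------------

    def _oob_masks(self, n: int) -> np.ndarray:
        masks = np.empty((len(self.trees), n), dtype=bool)
        for t, tree in enumerate(self.trees):
            masks[t] = np.bincount(tree.bootstrap, minlength=n) == 0
        return masks

    def oob_predict(self, X: np.ndarray, y: Sequence) -> tuple[np.ndarray, np.ndarray, float]:
        """OOB class distributions, coverage mask, and OOB MAP accuracy.

        Each row's distribution aggregates votes only from trees whose
        bootstrap excluded it; rows no tree excluded are uncovered
        (all-NaN rows, ``covered`` False).
        """
        X = _validate_X(X)
        y = np.asarray(y)
        n = X.shape[0]
        votes = np.zeros((n, self.n_classes), dtype=np.int64)
        masks = self._oob_masks(n)
        for t, tree in enumerate(self.trees):
            oob = np.where(masks[t])[0]
            if oob.size:
                votes[oob, tree.predict_codes(X[oob])] += 1
        n_votes = votes.sum(axis=1)
        covered = n_votes > 0
        proba = np.full((n, self.n_classes), np.nan)
        proba[covered] = votes[covered] / n_votes[covered, None]
        if covered.any():
            map_call = self.classes[np.argmax(votes[covered], axis=1)]
            acc = float(np.mean(map_call == y[covered]))
        else:
            acc = float("nan")
        return proba, covered, acc

    def permutation_importance(
        self, X: np.ndarray, y: Sequence, rng: np.random.Generator
    ) -> ImportanceScores:
        """Breiman permutation importance over the training data.

        For each tree and each SNP used by that tree, the SNP column is
        permuted within the tree's OOB rows (one permutation per tree per
        SNP) and the OOB accuracy drop recorded.  SNPs a tree does not use
        contribute an exact zero drop.  Score = mean drop / SD of drops;
        an SD of zero is treated as 1 so scores stay finite (and a SNP never
        used by any tree scores exactly 0).
        """
        X = _validate_X(X)
        y = np.asarray(y)
        y_codes = np.searchsorted(self.classes, y)
        n, p = X.shape
        drops = np.zeros((len(self.trees), p), dtype=np.float64)
        masks = self._oob_masks(n)
        for t, tree in enumerate(self.trees):
            oob = np.where(masks[t])[0]
            if oob.size == 0:
                continue
            Xo = X[oob]
            base = float(np.mean(tree.predict_codes(Xo) == y_codes[oob]))
            for snp in tree.used_features():
                perm = rng.permutation(oob.size)
                Xp = Xo.copy()
                Xp[:, snp] = Xo[perm, snp]
                acc = float(np.mean(tree.predict_codes(Xp) == y_codes[oob]))
                drops[t, snp] = base - acc
        mean = drops.mean(axis=0)
        sd = drops.std(axis=0, ddof=0)
        denom = np.where(sd > 0, sd, 1.0)
        return ImportanceScores(
            snp_index=np.arange(p), score=mean / denom, mean_drop=mean, sd_drop=sd
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": [_json_label(c) for c in self.classes],
            "n_snps": self.n_snps,
            "snp_ids": self.snp_ids,
            "params": {
                "n_trees": self.params.n_trees,
                "m_try": self.params.m_try,
                "max_nodes": self.params.max_nodes,
                "seed": self.params.seed,
            },
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "children": t.children.tolist(),
                    "leaf_class": t.leaf_class.tolist(),
                    "bootstrap": t.bootstrap.tolist(),
                }
                for t in self.trees
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Forest":
        trees = [
            Tree(
                feature=np.array(t["feature"], dtype=np.int32),
                children=np.array(t["children"], dtype=np.int32),
                leaf_class=np.array(t["leaf_class"], dtype=np.int32),
                bootstrap=np.array(t["bootstrap"], dtype=np.int32),
            )
            for t in d["trees"]
        ]
        return cls(
            trees=trees,
            classes=np.array(d["classes"]),
            n_snps=d["n_snps"],
            params=ForestParams(**d["params"]),
            snp_ids=d.get("snp_ids"),
        )


def _json_label(c):
    return int(c) if isinstance(c, (np.integer, int)) else str(c)


def fit_forest(X: np.ndarray, y: Sequence, params: ForestParams,
               snp_ids: list[str] | None = None) -> Forest:
    """Fit an ensemble of ``params.n_trees`` trees, each on a size-N bootstrap.

    Deterministic given ``params.seed``: the bootstrap draws and per-node
    candidate draws all derive from one seeded generator in a fixed order.
    """
    X = _validate_X(X)
    y_arr = np.asarray(y)
    if len(y_arr) != X.shape[0]:
        raise ValueError("y length must match rows of X")
    classes = np.unique(y_arr)
    y_codes = np.searchsorted(classes, y_arr)
    if len(classes) == 1:
        warnings.warn(
            f"target has a single class ({classes[0]!r}); fitting a degenerate "
            "always-that-class model",
            stacklevel=2,
        )
    rng = np.random.default_rng(params.seed)
    n = X.shape[0]
    m = params.resolve_m_try(X.shape[1])  # validate eagerly
    y64 = y_codes.astype(np.int64)
    trees: list[Tree] = []
    for _ in range(params.n_trees):
        boot = rng.integers(0, n, size=n)
        trees.append(
            _build_tree(X, y64, len(classes), m, params.max_nodes, rng, boot)
        )
    return Forest(trees=trees, classes=classes, n_snps=X.shape[1],
                  params=params, snp_ids=snp_ids)
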