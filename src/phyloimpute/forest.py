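"""Bespoke regression-forest engine with phylogeny-aware split tie-breaking.

Trees use CART-style SSR (sum of squared residuals) splitting on midpoint
thresholds.  When two candidate features tie on SSR, the tie is broken
either uniformly at random or by a priority list derived from the
neighbor-joining Q-matrix: each OTU ranks the other OTUs by ascending Q
value, and the tied feature appearing earliest in the ranking of the OTU
being imputed wins.  Hyperparameters follow the convention that fractional
values are resolved against the dataset size at fit time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

_TIE_RTOL = 1e-9  # relative SSR tolerance under which features count as tied


@dataclass
class ForestConfig:
    """Random-forest hyperparameters.

    Fractional fields (``bootstrap_size``, ``max_features``, ``max_depth``,
    ``min_leaf``) lie in (0, 1] and are multiplied by the relevant dataset
    dimension when the forest is fitted; ``max_depth = -1`` disables the
    depth limit.  The two named profiles are the tuned defaults.
    """

    bootstrap: bool = False
    bootstrap_size: float = 1.0
    n_trees: int = 30
    max_features: float = 0.25
    max_depth: float = 1.0
    min_leaf: float = 0.01
    tiebreak: str = "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("bootstrap_size", "max_features", "min_leaf"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.max_depth != -1 and not (0.0 < self.max_depth <= 1.0):
            raise ValueError(f"max_depth must be in (0, 1] or -1, got {self.max_depth}")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.tiebreak not in ("random", "q_priority"):
            raise ValueError(f"unknown tiebreak {self.tiebreak!r}")

    @classmethod
    def non_bootstrap(cls, tiebreak: str = "random", seed: int | None = None) -> "ForestConfig":
        """Tuned profile without bootstrapping: 30 trees, 25% features."""
        return cls(bootstrap=False, n_trees=30, max_features=0.25,
                   max_depth=1.0, min_leaf=0.01, tiebreak=tiebreak, seed=seed)

    @classmethod
    def bootstrap_profile(cls, tiebreak: str = "random", seed: int | None = None) -> "ForestConfig":
        """Tuned bagging profile: 50 trees, full-size resamples, all features."""
        return cls(bootstrap=True, bootstrap_size=1.0, n_trees=50, max_features=1.0,
                   max_depth=1.0, min_leaf=0.13, tiebreak=tiebreak, seed=seed)


@dataclass
class PriorityTable:
    """Per-OTU ranking of the other OTUs by ascending Q-matrix value.

    ``lists[x]`` is a permutation of all indices except x; ``rank[x, j]``
    is j's position in x's list (large for j = x).
    """

    lists: list[np.ndarray]
    rank: np.ndarray

    def __len__(self) -> int:
        return len(self.lists)


def priority_table(q: np.ndarray) -> PriorityTable:
    """Build the tie-break priority lists from a Q-matrix.

    For each OTU x the other OTUs are sorted ascending by Q[x, .], ties by
    lowest index; the first entry is the OTU sharing the lowest Q value
    with x (the pair NJ would agglomerate first).
    """
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    if q.ndim != 2 or q.shape[1] != n or n < 3:
        raise ValueError("Q must be square with N >= 3")
    lists: list[np.ndarray] = []
    rank = np.full((n, n), n, dtype=int)
    for x in range(n):
        others = np.array([j for j in range(n) if j != x])
        order = others[np.argsort(q[x, others], kind="stable")]
        lists.append(order)
        rank[x, order] = np.arange(n - 1)
    return PriorityTable(lists=lists, rank=rank)


def resolve_fraction(fraction: float, n_rows: int, minimum: int = 1) -> int:
    """Turn a fractional hyperparameter into a count: max(minimum, ceil(f*n))."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if n_rows < 1 or minimum < 1:
        raise ValueError("n_rows and minimum must be positive")
    return max(minimum, math.ceil(fraction * n_rows))


@dataclass
class Split:
    feature: int          # column position in the training X
    threshold: float
    ssr: float


@dataclass
class _Node:
    value: float = 0.0
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class RegressionTree:
    root: _Node
    n_features: int

    def predict_one(self, x: np.ndarray) -> float:
        node = self.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.value


@dataclass
class RegressionForest:
    trees: list[RegressionTree]
    n_features: int


def _feature_best(x: np.ndarray, y: np.ndarray, min_leaf: int) -> tuple[float, float] | None:
    """Best (ssr, threshold) for one feature, or None if no legal split."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(ys)
    cum = np.cumsum(ys)
    cumsq = np.cumsum(ys * ys)
    ln = np.arange(1, n)
    ls, lq = cum[:-1], cumsq[:-1]
    rs, rq = cum[-1] - ls, cumsq[-1] - lq
    rn = n - ln
    ssr = (lq - ls * ls / ln) + (rq - rs * rs / rn)
    valid = (xs[1:] > xs[:-1]) & (ln >= min_leaf) & (rn >= min_leaf)
    if not valid.any():
        return None
    ssr = np.where(valid, ssr, np.inf)
    k = int(np.argmin(ssr))
    thr = 0.5 * (xs[k] + xs[k + 1])
    if thr >= xs[k + 1]:  # midpoint rounded onto the upper value
        thr = xs[k]       # same partition under the (<=) rule
    return max(float(ssr[k]), 0.0), float(thr)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    features: Sequence[int],
    *,
    min_leaf: int = 1,
    tiebreak: str = "random",
    rng: np.random.Generator | None = None,
    priorities: PriorityTable | None = None,
    target_col: int | None = None,
    feature_ids: Sequence[int] | None = None,
) -> Split | None:
    """SSR-minimizing (feature, midpoint threshold) over candidate features.

    Thresholds are midpoints of consecutive distinct sorted values; both
    children must hold at least ``min_leaf`` rows.  SSR ties (relative
    tolerance 1e-9) are resolved by the configured policy: ``random``
    draws uniformly among the tied features, ``q_priority`` picks the tied
    feature whose OTU appears earliest in the priority list of the OTU
    being imputed (``target_col``).  Returns None when no legal split
    exists.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) == 0 or np.ptp(y) == 0.0:
        return None  # pure node: no split can improve SSR
    results: list[Split] = []
    for pos in features:
        out = _feature_best(X[:, pos], y, min_leaf)
        if out is not None:
            results.append(Split(feature=int(pos), threshold=out[1], ssr=out[0]))
    if not results:
        return None
    best = min(r.ssr for r in results)
    tied = [r for r in results
            if math.isclose(r.ssr, best, rel_tol=_TIE_RTOL, abs_tol=0.0) or r.ssr == best]
    if len(tied) == 1:
        return tied[0]
    if tiebreak == "q_priority":
        if priorities is None or target_col is None:
            raise ValueError("q_priority tie-break needs priorities and target_col")
        ids = list(feature_ids) if feature_ids is not None else list(range(X.shape[1]))
        return min(tied, key=lambda r: priorities.rank[target_col, ids[r.feature]])
    rng = rng if rng is not None else np.random.default_rng()
    return tied[int(rng.integers(len(tied)))]


def _grow(
    X: np.ndarray,
    y: np.ndarray,
    rows: np.ndarray,
    depth: int,
    *,
    depth_limit: int | None,
    min_leaf: int,
    n_sub_features: int,
    tiebreak: str,
    rng: np.random.Generator,
    priorities: PriorityTable | None,
    target_col: int | None,
    feature_ids: Sequence[int],
) -> _Node:
    y_sub = y[rows]
    node = _Node(value=float(y_sub.mean()))
    if (depth_limit is not None and depth >= depth_limit) or len(rows) < 2 * min_leaf:
        return node
    if np.ptp(y_sub) == 0.0:
        return node  # pure node
    n_feat = X.shape[1]
    feats = rng.choice(n_feat, size=min(n_sub_features, n_feat), replace=False)
    split = best_split(
        X[rows], y_sub, sorted(int(f) for f in feats),
        min_leaf=min_leaf, tiebreak=tiebreak, rng=rng,
        priorities=priorities, target_col=target_col, feature_ids=feature_ids,
    )
    if split is None:
        return node
    go_left = X[rows, split.feature] <= split.threshold
    if not go_left.any() or go_left.all():  # degenerate partition: stay a leaf
        return node
    kw = dict(depth_limit=depth_limit, min_leaf=min_leaf,
              n_sub_features=n_sub_features, tiebreak=tiebreak, rng=rng,
              priorities=priorities, target_col=target_col, feature_ids=feature_ids)
    node.feature = split.feature
    node.threshold = split.threshold
    node.left = _grow(X, y, rows[go_left], depth + 1, **kw)
    node.right = _grow(X, y, rows[~go_left], depth + 1, **kw)
    return node


def fit_forest(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    target_col: int | None = None,
    config: ForestConfig | None = None,
    priorities: PriorityTable | None = None,
    rng: np.random.Generator | int | None = None,
    feature_ids: Sequence[int] | None = None,
) -> RegressionForest:
    """Fit an ensemble of SSR-split regression trees.

    Each tree trains on a with-replacement resample when bootstrapping is
    enabled (size resolved from ``bootstrap_size``), otherwise on all
    rows; at every node a fresh random feature subset of resolved size is
    drawn.  ``feature_ids`` maps X columns to OTU indices so the
    Q-priority tie-break can look features up in the priority table.
    A single seeded generator, split into per-tree substreams, drives
    bootstrap draws, feature subsets and random tie-breaks.
    """
    X = np.atleast_2d(np.asarray(X_obs, dtype=float))
    y = np.asarray(y_obs, dtype=float)
    if X.shape[0] != len(y) or len(y) < 1:
        raise ValueError("X_obs rows must match y_obs length >= 1")
    config = config or ForestConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    n_rows, n_feat = X.shape
    min_leaf = resolve_fraction(config.min_leaf, n_rows)
    n_sub = resolve_fraction(config.max_features, n_feat)
    depth_limit = None if config.max_depth == -1 else resolve_fraction(config.max_depth, n_rows)
    boot_n = resolve_fraction(config.bootstrap_size, n_rows)
    ids = list(feature_ids) if feature_ids is not None else list(range(n_feat))

    trees: list[RegressionTree] = []
    for tree_rng in rng.spawn(config.n_trees):
        if config.bootstrap:
            rows = tree_rng.choice(n_rows, size=boot_n, replace=True)
        else:
            rows = np.arange(n_rows)
        root = _grow(
            X, y, rows, 0,
            depth_limit=depth_limit, min_leaf=min_leaf, n_sub_features=n_sub,
            tiebreak=config.tiebreak, rng=tree_rng,
            priorities=priorities, target_col=target_col, feature_ids=ids,
        )
        trees.append(RegressionTree(root=root, n_features=n_feat))
    return RegressionForest(trees=trees, n_features=n_feat)


def predict_forest(forest: RegressionForest, X_miss: np.ndarray) -> np.ndarray:
    """Average the per-tree leaf predictions for each query row."""
    X = np.atleast_2d(np.asarray(X_miss, dtype=float))
    if X.shape[1] != forest.n_features:
        raise ValueError(
            f"query has {X.shape[1]} features, forest trained on {forest.n_features}"
        )
    out = np.zeros(X.shape[0])
    for i, x in enumerate(X):
        out[i] = sum(t.predict_one(x) for t in forest.trees) / len(forest.trees)
    return out
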