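"""Synthetic ground truth: random trees, additive/noisy matrices, masks.

Topologies are uniform over unrooted binary trees (random sequential
attachment: each new leaf subdivides a uniformly chosen edge).  Branch
lengths are i.i.d. positive draws; patristic distances of the resulting
tree give an exactly additive matrix, optionally perturbed by symmetric
multiplicative lognormal noise (mean 1, chosen coefficient of variation)
so distances stay positive.  Masks come from
:func:`phyloimpute.matrix_core.inject_missing`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .matrix_core import DistanceMatrix, inject_missing
from .neighbor_joining import PhyloTree, _build_dendropy, patristic_matrix


@dataclass
class BranchDist:
    """Branch-length distribution: uniform(a, b) or exponential(mean).

    Defaults to uniform(0.1, 1.0) substitutions/site, a realistic range
    for inter-species evolutionary distances.
    """

    kind: str = "uniform"
    a: float = 0.1
    b: float = 1.0
    mean: float = 0.3

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "uniform":
            if not (0 < self.a < self.b):
                raise ValueError("uniform branch lengths need 0 < a < b")
            return rng.uniform(self.a, self.b, size)
        if self.kind == "exponential":
            # shift slightly away from zero so lengths are strictly positive
            return rng.exponential(self.mean, size) + 1e-9
        raise ValueError(f"unknown branch distribution {self.kind!r}")


@dataclass
class SyntheticInstance:
    truth_tree: PhyloTree
    full_matrix: DistanceMatrix
    mask: np.ndarray
    seed: int | None
    params: dict[str, Any] = field(default_factory=dict)


def _random_topology(n: int, rng: np.random.Generator) -> tuple[dict, list]:
    """Uniform unrooted binary topology over leaves 0..n-1.

    Returns (adjacency, edge list); internal ids start at n, the first
    internal node is the center of the initial 3-leaf star.
    """
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    edges: list[tuple[int, int]] = []

    def connect(a: int, b: int) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
        edges.append((a, b))

    center = n
    next_id = n + 1
    for leaf in range(3):
        connect(center, leaf)
    for leaf in range(3, n):
        a, b = edges[int(rng.integers(len(edges)))]
        adj[a].remove(b)
        adj[b].remove(a)
        edges.remove((a, b))
        u = next_id
        next_id += 1
        connect(a, u)
        connect(u, b)
        connect(u, leaf)
    return adj, edges


def random_tree(
    n: int,
    branch_dist: BranchDist | None = None,
    rng: np.random.Generator | int | None = None,
) -> PhyloTree:
    """Random unrooted bifurcating tree with strictly positive branch lengths."""
    if n < 4:
        raise ValueError("random_tree needs n >= 4")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    branch_dist = branch_dist or BranchDist()
    adj, edges = _random_topology(n, rng)
    lengths = branch_dist.sample(rng, len(edges))
    edge_len = {
        (min(a, b), max(a, b)): float(ln) for (a, b), ln in zip(edges, lengths)
    }
    labels = tuple(f"t{i + 1}" for i in range(n))
    return _build_dendropy(adj, edge_len, labels, root=n)


def make_instance(
    n: int,
    branch_dist: BranchDist | None = None,
    noise_cv: float = 0.0,
    missing_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
    seed: int | None = None,
) -> SyntheticInstance:
    """Ground-truth tree + (optionally noisy) matrix + missingness mask.

    ``noise_cv = 0`` yields an exactly additive matrix; otherwise every
    off-diagonal pair is multiplied by one shared lognormal factor with
    unit mean and coefficient of variation ``noise_cv``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(seed if rng is None else rng)
    branch_dist = branch_dist or BranchDist()
    tree = random_tree(n, branch_dist, rng)
    labels = tuple(f"t{i + 1}" for i in range(n))
    full = patristic_matrix(tree, labels=labels)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        iu = np.triu_indices(n, k=1)
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(iu[0]))
        v = full.values
        v[iu] *= factors
        v.T[iu] = v[iu]
        full = DistanceMatrix(labels, v)
    if missing_fraction > 0:
        mask = inject_missing(full, missing_fraction, rng)
    else:
        mask = np.zeros((n, n), dtype=bool)
    return SyntheticInstance(
        truth_tree=tree, full_matrix=full, mask=mask, seed=seed,
        params={
            "n": n, "branch_dist": branch_dist, "noise_cv": noise_cv,
            "missing_fraction": missing_fraction,
        },
    )


def nearest_neighbor_interchange(
    tree: PhyloTree, rng: np.random.Generator | int | None = None
) -> PhyloTree:
    """One NNI at a random internal edge: swaps a subtree across the edge.

    The returned copy differs from the input by exactly one nontrivial
    bipartition, i.e. RF distance 2.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    t = tree.clone(depth=1)
    candidates = [
        nd for nd in t.preorder_node_iter()
        if not nd.is_leaf() and nd is not t.seed_node and nd.parent_node is not None
    ]
    if not candidates:
        raise ValueError("tree has no internal edge for an NNI")
    node = candidates[int(rng.integers(len(candidates)))]
    parent = node.parent_node
    siblings = [c for c in parent.child_nodes() if c is not node]
    sib = siblings[int(rng.integers(len(siblings)))]
    child = node.child_nodes()[int(rng.integers(len(node.child_nodes())))]
    parent.remove_child(sib)
    node.remove_child(child)
    parent.add_child(child)
    node.add_child(sib)
    return t
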