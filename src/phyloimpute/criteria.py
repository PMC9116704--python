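"""Phylogenetic scoring and topological comparison.

Least-squares fit S = sum_{i != j} (d_ij - theta_ij)^2 between a distance
matrix and a tree's patristic distances (ordered pairs, so each unordered
pair counts twice); minimum-evolution score (total branch length);
Robinson-Foulds distance as the symmetric difference of nontrivial
bipartition sets; and its normalization NRF = RF / (2N - 6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DistanceMatrixError
from .matrix_core import DistanceMatrix
from .neighbor_joining import PhyloTree, patristic_matrix


@dataclass
class ScoreReport:
    """Per-run scores: LS fit, total branch length, RF and normalized RF."""

    ls: float
    me: float
    rf: int
    nrf: float

    @property
    def nrf_pct(self) -> float:
        return 100.0 * self.nrf


def ls_score(d: DistanceMatrix, tree: PhyloTree) -> float:
    """Least-squares discrepancy between a matrix and a tree.

    Zero iff the matrix is additive and realized by the tree.
    """
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if leaves != set(d.labels):
        raise DistanceMatrixError(
            f"tree leaves do not match matrix labels: {sorted(leaves ^ set(d.labels))}"
        )
    theta = patristic_matrix(tree, labels=d.labels)
    diff = d.values - theta.values
    return float(np.sum(diff * diff))


def me_score(tree: PhyloTree) -> float:
    """Minimum-evolution criterion: the tree's total branch length."""
    return float(sum(e.length for e in tree.preorder_edge_iter() if e.length is not None))


def _nontrivial_splits(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial bipartitions, canonicalized by the side excluding a
    fixed reference leaf (the lexicographically smallest label)."""
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(labels)
    n = len(labels)
    splits: set[frozenset] = set()
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
            continue
        side = frozenset().union(*(below[id(c)] for c in node.child_nodes()))
        below[id(node)] = side
        if node is tree.seed_node:
            continue
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset(labels - side) if ref in side else side)
    return splits


def rf_distance(a: PhyloTree, b: PhyloTree) -> int:
    """Robinson-Foulds distance: |splits(A) symmetric-difference splits(B)|.

    Counts nontrivial bipartitions only; 0 iff the unrooted topologies
    coincide, at most 2N - 6 for a pair of bifurcating trees.
    """
    la = {lf.taxon.label for lf in a.leaf_node_iter()}
    lb = {lf.taxon.label for lf in b.leaf_node_iter()}
    if la != lb:
        raise DistanceMatrixError(f"leaf sets differ: {sorted(la ^ lb)}")
    if len(la) < 4:
        raise DistanceMatrixError("RF distance needs >= 4 leaves")
    return len(_nontrivial_splits(a) ^ _nontrivial_splits(b))


def nrf(rf: int, n: int) -> float:
    """Normalized RF in [0, 1]: rf / (2N - 6); x100 gives the percentage
    of topological error the imputation introduced."""
    if n < 4:
        raise ValueError("NRF undefined for N < 4 (zero denominator)")
    if not (0 <= rf <= 2 * n - 6):
        raise ValueError(f"rf={rf} outside [0, {2 * n - 6}] for N={n}")
    return rf / (2.0 * n - 6.0)


def score_report(d: DistanceMatrix, tree: PhyloTree, truth: PhyloTree) -> ScoreReport:
    """Bundle LS/ME of (d, tree) with RF/NRF of tree against the truth."""
    rf = rf_distance(tree, truth)
    return ScoreReport(ls=ls_score(d, tree), me=me_score(tree),
                       rf=rf, nrf=nrf(rf, d.n))
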