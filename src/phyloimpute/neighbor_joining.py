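"""Neighbor-joining, Q-matrix, patristic distances, and Newick I/O.

The agglomeration is the standard Saitou-Nei scheme: repeatedly join the
pair of active nodes minimizing Q_ij = (N-2) d_ij - S_i - S_j, attach the
pair to a fresh internal node with the usual limb-length formulas, and
reduce the matrix.  Ties in the Q minimum are broken deterministically by
lowest (i, j) index pair, and negative branch lengths are kept as computed
(no clamping) so least-squares and patristic scores are exact.  Trees are
dendropy objects, serialized unrooted with a trifurcating root.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .errors import DistanceMatrixError, NewickParseError
from .matrix_core import DistanceMatrix

PhyloTree = dendropy.Tree


def _values(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    return d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)


def q_matrix(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Q_ij = (N-2) d_ij - S_i - S_j with S_x the full row sum.

    The diagonal is undefined and set to +inf so that row minima always
    point at another OTU.
    """
    v = _values(d)
    n = v.shape[0]
    if n < 3:
        raise DistanceMatrixError("Q-matrix needs N >= 3")
    s = v.sum(axis=1)
    q = (n - 2) * v - s[:, None] - s[None, :]
    np.fill_diagonal(q, np.inf)
    return q


def _build_dendropy(
    adj: dict[int, list[int]],
    edge_len: dict[tuple[int, int], float],
    labels: tuple[str, ...],
    root: int,
) -> PhyloTree:
    """Turn an adjacency map over node ids (leaves = 0..N-1) into a tree."""
    tns = dendropy.TaxonNamespace()
    taxa = [tns.new_taxon(label=lab) for lab in labels]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = False

    def attach(parent_node: dendropy.Node, node_id: int, parent_id: int | None) -> None:
        for nbr in adj[node_id]:
            if nbr == parent_id:
                continue
            ln = edge_len[(min(node_id, nbr), max(node_id, nbr))]
            child = parent_node.new_child(edge_length=ln)
            if nbr < len(labels):
                child.taxon = taxa[nbr]
            attach(child, nbr, node_id)

    attach(tree.seed_node, root, None)
    return tree


def nj_tree(d: DistanceMatrix) -> PhyloTree:
    """Unrooted bifurcating neighbor-joining tree for a complete matrix.

    Deterministic: the joined pair is the lexicographically first (i, j)
    attaining the Q minimum.  On an additive matrix the generating
    topology is recovered and patristic distances reproduce the input.
    """
    v = _values(d).copy()
    labels = d.labels
    n = v.shape[0]
    if n < 3:
        raise DistanceMatrixError("neighbor joining needs N >= 3")
    if not d.is_symmetric():
        raise DistanceMatrixError("neighbor joining needs a symmetric matrix")

    active = list(range(n))          # node ids, leaves are 0..n-1
    next_id = n
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    edge_len: dict[tuple[int, int], float] = {}

    def connect(a: int, b: int, ln: float) -> None:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
        edge_len[(min(a, b), max(a, b))] = float(ln)

    while len(active) > 3:
        m = len(active)
        s = v.sum(axis=1)
        q = (m - 2) * v - s[:, None] - s[None, :]
        # keep only i < j; row-major argmin gives the lexicographic tie rule
        q[np.tril_indices(m)] = np.inf
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        limb_i = 0.5 * v[i, j] + (s[i] - s[j]) / (2.0 * (m - 2))
        limb_j = v[i, j] - limb_i
        u = next_id
        next_id += 1
        connect(u, active[i], limb_i)
        connect(u, active[j], limb_j)
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = 0.5 * (v[i, keep] + v[j, keep] - v[i, j])
        v = v[np.ix_(keep, keep)]
        v = np.pad(v, ((0, 1), (0, 1)))
        v[-1, :-1] = d_new
        v[:-1, -1] = d_new
        active = [active[k] for k in keep] + [u]

    # final 3-way join at a central node
    a, b, c = active
    la = 0.5 * (v[0, 1] + v[0, 2] - v[1, 2])
    lb = 0.5 * (v[0, 1] + v[1, 2] - v[0, 2])
    lc = 0.5 * (v[0, 2] + v[1, 2] - v[0, 1])
    center = next_id
    connect(center, a, la)
    connect(center, b, lb)
    connect(center, c, lc)
    return _build_dendropy(adj, edge_len, labels, center)


def patristic_matrix(
    tree: PhyloTree, labels: tuple[str, ...] | None = None
) -> DistanceMatrix:
    """Path-length (patristic) distances between all pairs of leaves."""
    leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if labels is None:
        labels = tuple(leaf_labels)
    if set(labels) != set(leaf_labels):
        raise DistanceMatrixError(
            f"requested labels do not match tree leaves: "
            f"{sorted(set(labels) ^ set(leaf_labels))}"
        )
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            out[i, j] = out[j, i] = dist
    return DistanceMatrix(labels, out)


def write_newick(tree: PhyloTree) -> str:
    """Serialize with branch lengths; unrooted trees keep a trifurcating root."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; malformed input raises with reader position."""
    try:
        return dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
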