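"""Distance-based trees: neighbour-joining, bootstrap support, Newick I/O.

Trees are :class:`dendropy.Tree` objects throughout the package; this
module adds a validated square distance-matrix container, a Saitou-Nei
neighbour-joining implementation with deterministic tie-breaking and
PHYLIP-compatible handling of negative branch-length estimates, and
bipartition-based bootstrap support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
    "read_newick",
    "write_newick",
    "read_phylip_lower",
    "midpoint_root",
]


@dataclass
class DistanceMatrix:
    """Labelled symmetric nonnegative matrix with zero diagonal."""

    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix is not symmetric (tolerance 1e-12)")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(m < 0):
            raise ValueError("distances must be nonnegative")
        self.matrix = m

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(labels=[str(c) for c in df.columns], matrix=df.to_numpy(float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour-joining on a distance matrix.

    Standard Q-criterion agglomeration producing an unrooted tree
    (trifurcating seed node). Ties in Q are broken deterministically by
    the lexicographically lowest label pair, each cluster being named by
    its smallest member tip. Negative branch-length estimates (possible
    on non-additive input such as chord-distance matrices) are clamped to
    zero with the deficit transferred to the sister edge, and logged.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbour-joining needs >= 3 taxa")
    taxa = dendropy.TaxonNamespace(d.labels)
    nodes = []
    for label in d.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    keys = list(d.labels)  # cluster sort key: smallest member tip label
    dist = d.matrix.copy()
    active = list(range(n))

    def clamp(pair):
        (node_i, li), (node_j, lj) = pair
        if li < 0:
            logger.info("clamping negative NJ branch %.4g on %s", li, keys)
            lj += li
            li = 0.0
        if lj < 0:
            logger.info("clamping negative NJ branch %.4g", lj)
            li += lj
            lj = 0.0
        return (node_i, max(li, 0.0)), (node_j, max(lj, 0.0))

    while len(active) > 2:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                if q[ai, aj] <= qmin + 1e-12:
                    pair_key = tuple(sorted((keys[active[ai]], keys[active[aj]])))
                    if best is None or pair_key < best[0]:
                        best = (pair_key, ai, aj)
        _, ai, aj = best
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (totals[ai] - totals[aj]) / (2 * (m - 2))
        lj = dij - li
        (node_i, li), (node_j, lj) = clamp(((nodes[i], li), (nodes[j], lj)))
        parent = dendropy.Node()
        parent.add_child(node_i)
        parent.add_child(node_j)
        node_i.edge.length = li
        node_j.edge.length = lj
        # distances from the new cluster to the rest
        new_row = np.zeros(dist.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (dist[i, k] + dist[j, k] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    if len(active) == 2:
        i, j = active
        # attach the penultimate cluster to the last with the remaining edge
        root = nodes[j] if nodes[j].is_internal() else nodes[i]
        other = nodes[i] if root is nodes[j] else nodes[j]
        root.add_child(other)
        other.edge.length = max(dist[i, j], 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as label sets, normalized to exclude a fixed
    reference tip (the lexicographically smallest label)."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    full = frozenset(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = full - side
        if 2 <= len(side) <= len(labels) - 2:
            out.add(side)
    return out


def bootstrap_support(
    original: dendropy.Tree, replicates: list[dendropy.Tree]
) -> dendropy.Tree:
    """Annotate internal edges with integer-percent bootstrap support.

    Support of an internal edge = percentage of replicate trees containing
    the same bipartition of the tip set. The returned tree is a clone of
    ``original`` with supports stored as internal-node labels and in
    ``node.support``.
    """
    orig_tips = {leaf.taxon.label for leaf in original.leaf_node_iter()}
    for rep in replicates:
        tips = {leaf.taxon.label for leaf in rep.leaf_node_iter()}
        if tips != orig_tips:
            raise ValueError(
                f"replicate tip set mismatch: {sorted(tips ^ orig_tips)}"
            )
    rep_biparts = [bipartitions(rep) for rep in replicates]
    labels = sorted(orig_tips)
    ref = labels[0]
    full = frozenset(labels)
    annotated = original.clone(depth=1)
    for node in annotated.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = full - side
        if not (2 <= len(side) <= len(labels) - 2):
            continue
        count = sum(side in rb for rb in rep_biparts)
        support = int(round(100.0 * count / len(replicates)))
        node.label = str(support)
        node.support = support
    return annotated


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a tree (internal labels preserved)."""
    return dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick with branch lengths and internal labels."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def read_phylip_lower(text: str) -> DistanceMatrix:
    """Read a PHYLIP lower-triangular distance file."""
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    m = np.zeros((n, n))
    for i, row in enumerate(rows):
        for j, v in enumerate(row[:i]):
            m[i, j] = m[j, i] = v
    return DistanceMatrix(labels=labels, matrix=m)


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-root a clone of an unrooted tree."""
    rooted = tree.clone(depth=1)
    rooted.reroot_at_midpoint(update_bipartitions=True)
    rooted.is_rooted = True
    return rooted
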