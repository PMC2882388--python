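"""Uncorrected p-distances and neighbor-joining trees.

Distances are proportions of differing sites with pairwise deletion of
gap/ambiguous columns. Tree construction is the Saitou-Nei neighbor-joining
algorithm with two determinism guarantees the downstream reports rely on:
ties in the Q criterion are broken by the lexicographically smallest pair of
cluster labels (a cluster is labelled by its smallest leaf id), and negative
branch lengths are clamped to zero with the deficit logged. Trees are held as
dendropy objects, so Newick round-tripping and rerooting use that library.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .seq_io import Msa, NUCLEOTIDE

logger = logging.getLogger(__name__)

_Q_TIE_TOL = 1e-12


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        m = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", m)
        k = len(self.labels)
        if m.shape != (k, k):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrix must be symmetric with zero diagonal")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """Pairwise uncorrected p-distances with pairwise deletion.

    Columns where either member of a pair carries a gap, ``X`` (protein) or
    ``N`` (nucleotide) are skipped for that pair only. A pair with zero
    comparable sites is an error naming the pair.
    """
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows")
    skip = {"-", "N"} if msa.rows[0].alphabet == NUCLEOTIDE else {"-", "X"}
    n = msa.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = msa.rows[i].residues
            b = msa.rows[j].residues
            used = diffs = 0
            for x, y in zip(a, b):
                if x in skip or y in skip:
                    continue
                used += 1
                diffs += x != y
            if used == 0:
                raise ValueError(
                    f"no comparable sites between {msa.rows[i].id!r} and {msa.rows[j].id!r}"
                )
            d[i, j] = d[j, i] = diffs / used
    return DistanceMatrix(tuple(r.id for r in msa.rows), d)


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("negative NJ branch length %.6g at %s clamped to 0", length, context)
        return 0.0
    return length


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; returns an unrooted dendropy tree.

    The active pair at each step minimises
    ``Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)``; ties within
    1e-12 go to the lexicographically smallest (label_i, label_j) pair.
    """
    k = len(dm.labels)
    if k < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    labels: list[str] = []  # tie-break label = smallest leaf id in cluster
    for lab in dm.labels:
        node = dendropy.Node(taxon=ns.new_taxon(lab))
        nodes.append(node)
        labels.append(lab)
    d = dm.d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - _Q_TIE_TOL or (
                    abs(q - best[0]) <= _Q_TIE_TOL and key < best[1]
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = _clamp(li, labels[i])
        parent.add_child(nodes[j])
        nodes[j].edge.length = _clamp(lj, labels[j])
        new_row = np.array(
            [(d[i, x] + d[j, x] - d[i, j]) / 2 for x in range(m)]
        )
        keep = [x for x in range(m) if x not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_row[keep]])
        d = np.hstack([d, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
        labels = [labels[x] for x in keep] + [min(labels[i], labels[j])]

    # terminal trifurcation: three-point closed form
    root = dendropy.Node()
    (i, j, kk) = (0, 1, 2)
    lens = (
        (d[i, j] + d[i, kk] - d[j, kk]) / 2,
        (d[i, j] + d[j, kk] - d[i, kk]) / 2,
        (d[i, kk] + d[j, kk] - d[i, j]) / 2,
    )
    for node, length, lab in zip(nodes, lens, labels):
        root.add_child(node)
        node.edge.length = _clamp(length, lab)
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def root_with_outgroup(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of the outgroup's pendant edge."""
    rooted = tree.clone(depth=1)
    leaf = None
    for lf in rooted.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == label:
            leaf = lf
            break
    if leaf is None:
        raise ValueError(f"outgroup label {label!r} not found among leaves")
    pendant = leaf.edge.length or 0.0
    rooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
    # reroot_at_edge places the new root on the edge; split the length evenly
    for child in rooted.seed_node.child_nodes():
        child.edge.length = pendant / 2
    rooted.is_rooted = True
    return rooted


def write_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths; labels quoted when needed."""
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


def read_newick(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick")
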