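"""Cell lineage tree inference: p-distances, UPGMA, Newick I/O.

Distances between cells are p-distances — the fraction of jointly observed
alignment sites at which two cells differ — computed with pairwise deletion
of missing states. Trees are inferred with UPGMA (average-linkage
agglomerative clustering), which yields rooted ultrametric trees; branch
lengths are in substitutions per site. Any rooted Newick tree (e.g. from an
external maximum-likelihood run) can be loaded and fed to the feature layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    """Raised when a Newick file cannot be parsed."""


@dataclass
class DistanceMatrix:
    """Symmetric matrix of pairwise distances with tip labels."""

    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.labels = list(self.labels)
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")

    @property
    def n(self) -> int:
        return len(self.labels)

    def write_phylip(self, path) -> None:
        """Write the square matrix in relaxed PHYLIP format."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + " ".join(f"{v:.10g}" for v in row) + "\n")


@dataclass
class CellTree:
    """A rooted, branch-length-weighted cell lineage tree.

    Wraps a :class:`dendropy.Tree`; tips are labelled with cell barcodes.
    Branch lengths are substitutions/site for inferred trees and mutation
    counts for simulated truth trees.
    """

    tree: dendropy.Tree
    ultrametric: bool = field(default=False)

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def tip_labels(self) -> list:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def root_to_tip_depths(self) -> dict:
        """Patristic depth of every tip from the root (missing lengths = 0)."""
        depths = {}
        stack = [(self.tree.seed_node, 0.0)]
        while stack:
            node, d = stack.pop()
            if node.is_leaf():
                depths[node.taxon.label] = d
            for ch in node.child_nodes():
                stack.append((ch, d + (ch.edge.length or 0.0)))
        return depths

    def check_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        depths = np.array(list(self.root_to_tip_depths().values()))
        if depths.size == 0:
            return True
        span = depths.max() - depths.min()
        return span <= rel_tol * max(depths.max(), 1.0e-300) or span == 0.0

    def as_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".17g",
            unquoted_underscores=True,
        )
        return s.strip()

    @classmethod
    def from_newick(cls, newick: str) -> "CellTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True, rooting="force-rooted"
            )
        except Exception as exc:
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        ct = cls(tree=tree)
        ct.ultrametric = ct.check_ultrametric()
        return ct

    @classmethod
    def from_children(cls, children: dict, edge_length: dict, tip_labels: dict,
                      root: int, ultrametric: bool = False) -> "CellTree":
        """Build from integer-indexed child lists.

        ``children[v]`` lists the children of internal node ``v``;
        ``edge_length[v]`` is the length of the edge above ``v``;
        ``tip_labels[v]`` labels leaf ``v``. Built iteratively so deep
        caterpillar trees do not hit the recursion limit.
        """
        taxa = dendropy.TaxonNamespace()
        nodes = {}
        order = []
        stack = [root]
        while stack:  # preorder
            v = stack.pop()
            order.append(v)
            stack.extend(children.get(v, ()))
        for v in order:
            node = dendropy.Node()
            node.edge.length = float(edge_length.get(v, 0.0)) if v != root else None
            if v not in children or not children[v]:
                node.taxon = taxa.new_taxon(str(tip_labels[v]))
            nodes[v] = node
        for v in order:
            for ch in children.get(v, ()):
                nodes[v].add_child(nodes[ch])
        tree = dendropy.Tree(taxon_namespace=taxa)
        tree.seed_node = nodes[root]
        ct = cls(tree=tree, ultrametric=ultrametric)
        return ct


def p_distance(a, pairwise_deletion: bool = True) -> DistanceMatrix:
    """p-distance matrix of a cell alignment.

    For each cell pair the distance is (# sites where both states are
    observed and differ) / (# sites where both are observed); '?' states are
    removed pairwise (the "raw" substitution model). With
    ``pairwise_deletion=False``, sites missing in *any* cell are dropped for
    all pairs (complete deletion). Pairs with zero comparable sites get
    distance 0; their count is logged.
    """
    states = a.state_codes()  # (n_cells, n_sites) uint8: 0=R, 1=A, 2=missing
    if states.shape[0] < 2:
        raise ValueError("p_distance needs at least 2 cells")
    if not pairwise_deletion:
        keep = ~(states == 2).any(axis=0)
        states = states[:, keep]
    valid = (states != 2)
    altm = (states == 1) & valid
    refm = (states == 0) & valid
    A = altm.astype(np.float64)
    R = refm.astype(np.float64)
    comparable = (A + R) @ (A + R).T
    differing = A @ R.T + R @ A.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(comparable > 0, differing / np.maximum(comparable, 1), 0.0)
    n_empty = int(((comparable <= 0).sum() - states.shape[0]) // 2)  # off-diagonal pairs
    if n_empty > 0:
        logger.warning("p_distance: %d cell pairs share no comparable sites; distance set to 0", n_empty)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(a.cells), d=d)


def upgma(dm: DistanceMatrix) -> CellTree:
    """UPGMA (average linkage) tree from a distance matrix.

    At each step the pair of clusters at minimal distance is merged; the new
    node is placed at height d/2 and distances to the remaining clusters are
    updated as size-weighted averages. Ties are broken by the smallest
    (row, col) index pair in the current cluster order (input tip order,
    then merge-creation order). The result is rooted, binary and ultrametric.
    """
    d = np.asarray(dm.d, dtype=float)
    n = dm.n
    if n < 2:
        raise ValueError("UPGMA needs at least 2 tips")
    if not np.allclose(d, d.T, rtol=0, atol=1e-12):
        raise ValueError("UPGMA requires a symmetric distance matrix")

    total = 2 * n - 1
    D = np.full((total, total), np.inf)
    D[:n, :n] = d
    np.fill_diagonal(D, np.inf)
    size = np.ones(total)
    height = np.zeros(total)
    children: dict = {}
    active = list(range(n))
    nxt = n
    while len(active) > 1:
        idx = np.asarray(active)
        sub = D[np.ix_(idx, idx)]
        k = int(np.argmin(sub))  # row-major first occurrence = smallest (row, col)
        i, j = divmod(k, len(idx))
        a, b = int(idx[i]), int(idx[j])
        h = D[a, b] / 2.0
        rest = np.asarray([x for x in active if x != a and x != b], dtype=int)
        if rest.size:
            D[nxt, rest] = (size[a] * D[a, rest] + size[b] * D[b, rest]) / (size[a] + size[b])
            D[rest, nxt] = D[nxt, rest]
        height[nxt] = h
        size[nxt] = size[a] + size[b]
        children[nxt] = (a, b)
        active = [x for x in active if x != a and x != b] + [nxt]
        nxt += 1

    root = total - 1
    edge_length = {}
    for v, (a, b) in children.items():
        for ch in (a, b):
            edge_length[ch] = max(height[v] - height[ch], 0.0)
    tip_labels = {i: dm.labels[i] for i in range(n)}
    ct = CellTree.from_children(children, edge_length, tip_labels, root=root, ultrametric=True)
    return ct


def write_newick(t: CellTree, path) -> None:
    """Write one tree as a Newick string terminated by ';'."""
    with open(path, "w") as fh:
        fh.write(t.as_newick() + "\n")


def read_newick(path) -> CellTree:
    """Read a rooted tree from a Newick file."""
    with open(path) as fh:
        text = fh.read()
    return CellTree.from_newick(text)


def infer_sample_trees(alignments) -> list:
    """Map p-distance + UPGMA over pseudo-replicate alignments."""
    trees = []
    for k, a in enumerate(alignments):
        try:
            trees.append(upgma(p_distance(a)))
        except Exception as exc:
            raise RuntimeError(f"tree inference failed for replicate {k}: {exc}") from exc
    return trees
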