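"""Tree-shape metrics: 31 named statistics of a cell lineage tree.

The metric set falls into five groups:

* **Group I** (8) — spectral: eigenvalues of distance/graph Laplacian
  transforms of the tree. The "modified graph Laplacian" (MGL) is
  ``diag(rowsums(P)) - P`` where P is the patristic distance matrix over
  *all* vertices (tips and internal nodes); its spectrum summarises the
  global branch-length geometry (largest eigenvalue, largest eigengap and
  its position, spectral skewness/kurtosis/entropy). The ordinary graph
  Laplacian of the tree graph supplies the algebraic connectivity ``AC_2``
  (unweighted) and the largest eigenvalue ``lmax_graph`` (branch-length
  weighted).
* **Group II** (7) — aggregated branch-length statistics, including an
  entropy over the branch-length distribution.
* **Group III** (8) — classical phylogenetic statistics from the
  biodiversity literature (Colless, Sackin, cherries, Pybus–Harvey gamma,
  treeness, B1, B2, maximal topological depth).
* **Group IV** (6) — summaries of the tip–tip and root–tip patristic
  distance matrices.
* **Group V** (2) — Laplacian spectrum extremes of the *square* of the
  (unweighted) tree graph, connecting vertices at edge-distance <= 2.

All metrics are pure functions of the tree, invariant to tip relabelling
and to the rotation order of children.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import kurtosis, skew

logger = logging.getLogger(__name__)

FEATURE_GROUPS = {
    # Group I — spectral
    "mMaxEigen": "I",
    "mMax_eigengap": "I",
    "eigengap_pos": "I",
    "spec_skewness": "I",
    "spec_kurtosis": "I",
    "spec_entropy": "I",
    "AC_2": "I",
    "lmax_graph": "I",
    # Group II — branch lengths
    "bl_total": "II",
    "bl_mean": "II",
    "bl_median": "II",
    "bl_var": "II",
    "bl_max": "II",
    "bl_entropy": "II",
    "bl_int_ext_ratio": "II",
    # Group III — classical topology/time statistics
    "colless_norm": "III",
    "sackin_norm": "III",
    "cherries_norm": "III",
    "gamma_stat": "III",
    "treeness": "III",
    "B1": "III",
    "B2": "III",
    "max_depth_topo": "III",
    # Group IV — tip distance matrix summaries
    "tipDist_mean": "IV",
    "tipDist_var": "IV",
    "tipDist_max": "IV",
    "tipDistNorm": "IV",
    "tipRootPatr": "IV",
    "tipRootPatr_var": "IV",
    # Group V — powergraph
    "pg_lmax": "V",
    "pg_AC2": "V",
}

FEATURE_NAMES = list(FEATURE_GROUPS)


@dataclass
class TreeFeatureVector:
    """The 31 named tree-shape metrics for one tree."""

    values: dict
    tree_id: str | None = None
    sample_id: str | None = None
    replicate_id: str | None = None
    group: dict = field(default_factory=lambda: dict(FEATURE_GROUPS))

    def __post_init__(self):
        missing = [k for k in FEATURE_NAMES if k not in self.values]
        extra = [k for k in self.values if k not in FEATURE_GROUPS]
        if missing or extra:
            raise ValueError(f"feature vector mismatch; missing={missing} extra={extra}")
        self.values = {k: float(self.values[k]) for k in FEATURE_NAMES}

    def to_series(self):
        import pandas as pd

        return pd.Series(self.values, name=self.tree_id)


# ---------------------------------------------------------------------------
# tree -> arrays


class _TreeGraph:
    """Array view of a rooted tree: vertices, edges, depths, tip flags."""

    def __init__(self, ct):
        nodes = []
        stack = [ct.tree.seed_node]
        while stack:
            nd = stack.pop()
            nodes.append(nd)
            stack.extend(nd.child_nodes())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        elen = np.zeros(n, dtype=float)
        is_tip = np.zeros(n, dtype=bool)
        labels = [None] * n
        for nd in nodes:
            i = index[id(nd)]
            if nd.is_leaf():
                is_tip[i] = True
                labels[i] = nd.taxon.label if nd.taxon else str(i)
            for ch in nd.child_nodes():
                j = index[id(ch)]
                parent[j] = i
                elen[j] = float(ch.edge.length or 0.0)
        self.nodes = nodes
        self.parent = parent
        self.edge_length = elen
        self.is_tip = is_tip
        self.labels = labels
        self.root = index[id(ct.tree.seed_node)]
        self.n_vertices = n
        self.n_tips = int(is_tip.sum())
        # children lists
        self.children = [[] for _ in range(n)]
        for j in range(n):
            if parent[j] >= 0:
                self.children[parent[j]].append(j)

    def depths(self, topological: bool = False) -> np.ndarray:
        d = np.zeros(self.n_vertices, dtype=float)
        order = self._preorder()
        for v in order:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + (1.0 if topological else self.edge_length[v])
        return d

    def _preorder(self):
        order = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order

    def _postorder(self):
        return list(reversed(self._preorder()))

    def adjacency(self, weighted: bool) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for j in range(self.n_vertices):
            p = self.parent[j]
            if p < 0:
                continue
            w = self.edge_length[j] if weighted else 1.0
            rows += [p, j]
            cols += [j, p]
            vals += [w, w]
        return sp.csr_matrix((vals, (rows, cols)), shape=(self.n_vertices, self.n_vertices))

    def patristic_all(self) -> np.ndarray:
        """Pairwise patristic distances over all vertices (dense).

        Uses d(u,v) = depth(u) + depth(v) - 2 depth(lca(u,v)); the LCA-depth
        matrix is filled by one vectorized block assignment per internal
        node (each vertex pair has exactly one LCA), which is much faster
        than all-pairs Dijkstra on large trees.
        """
        n = self.n_vertices
        if n == 1:
            return np.zeros((1, 1))
        depth = self.depths(topological=False)
        lca_depth = np.zeros((n, n))
        desc: dict = {}
        for v in self._postorder():
            kids = self.children[v]
            if not kids:
                desc[v] = np.array([v], dtype=np.int64)
                continue
            groups = [desc.pop(c) for c in kids]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    lca_depth[np.ix_(groups[i], groups[j])] = depth[v]
                    lca_depth[np.ix_(groups[j], groups[i])] = depth[v]
                lca_depth[groups[i], v] = depth[v]
                lca_depth[v, groups[i]] = depth[v]
            desc[v] = np.concatenate([np.array([v], dtype=np.int64)] + groups)
        P = depth[:, None] + depth[None, :] - 2.0 * lca_depth
        np.fill_diagonal(P, 0.0)
        return np.maximum(P, 0.0)


def _laplacian(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj, dtype=float)
    return np.diag(a.sum(axis=1)) - a


# ---------------------------------------------------------------------------
# Group I


def spectral_features(t) -> dict:
    """Spectral (Group I) metrics; requires at least 3 tips."""
    g = _TreeGraph(t)
    if g.n_tips < 3:
        raise ValueError(f"spectral features need >= 3 tips, got {g.n_tips}")
    P = g.patristic_all()
    mgl = np.diag(P.sum(axis=1)) - P
    lam = np.linalg.eigvalsh(mgl)  # ascending
    desc = lam[::-1]
    gaps = desc[:-1] - desc[1:]
    gi = int(np.argmax(gaps))
    pos = np.clip(lam, 0.0, None)
    tot = pos.sum()
    if tot > 0:
        p = pos / tot
        nz = p > 0
        entropy = float(-(p[nz] * np.log(p[nz])).sum())
    else:
        entropy = 0.0
    l0 = np.linalg.eigvalsh(_laplacian(g.adjacency(weighted=False).toarray()))
    lw = np.linalg.eigvalsh(_laplacian(g.adjacency(weighted=True).toarray()))
    return {
        "mMaxEigen": float(desc[0]),
        "mMax_eigengap": float(gaps[gi]),
        "eigengap_pos": float(gi + 1),
        "spec_skewness": float(skew(lam)),
        "spec_kurtosis": float(kurtosis(lam)),  # excess kurtosis
        "spec_entropy": entropy,
        "AC_2": float(l0[1]),
        "lmax_graph": float(lw[-1]),
    }


# ---------------------------------------------------------------------------
# Group II


def branch_stats(t) -> dict:
    """Branch-length (Group II) metrics; requires at least one edge."""
    g = _TreeGraph(t)
    has_edge = g.parent >= 0
    if not has_edge.any():
        raise ValueError("branch statistics need at least one edge")
    b = g.edge_length[has_edge]
    internal = ~g.is_tip[has_edge]
    total = float(b.sum())
    if total > 0:
        p = b / total
        nz = p > 0
        entropy = float(-(p[nz] * np.log(p[nz])).sum())
    else:
        entropy = 0.0
    term_sum = float(b[~internal].sum())
    int_sum = float(b[internal].sum())
    if term_sum > 0:
        ratio = int_sum / term_sum
    else:
        logger.debug("branch_stats: terminal branch length sum is 0; bl_int_ext_ratio set to 0")
        ratio = 0.0
    return {
        "bl_total": total,
        "bl_mean": float(b.mean()),
        "bl_median": float(np.median(b)),
        "bl_var": float(b.var()),  # population variance
        "bl_max": float(b.max()),
        "bl_entropy": entropy,
        "bl_int_ext_ratio": ratio,
    }


# ---------------------------------------------------------------------------
# Group III


def _binarized(g: _TreeGraph):
    """Topology arrays with unary chains collapsed and polytomies resolved.

    Returns (children, parent, edge_length, is_tip) over a relabelled vertex
    set. Polytomies are resolved left-to-right with zero-length edges;
    unary internal vertices are collapsed into their child edge.
    """
    # collapse unary chains (root included if unary)
    children = [list(c) for c in g.children]
    parent = g.parent.copy()
    elen = g.edge_length.copy()
    alive = np.ones(g.n_vertices, dtype=bool)
    root = g.root
    changed = True
    while changed:
        changed = False
        for v in range(g.n_vertices):
            if not alive[v] or g.is_tip[v]:
                continue
            if len(children[v]) == 1:
                (c,) = children[v]
                p = parent[v]
                elen[c] += elen[v]
                parent[c] = p
                if p >= 0:
                    children[p][children[p].index(v)] = c
                else:
                    root = c
                alive[v] = False
                changed = True
    # resolve polytomies with zero-length edges
    extra_children = {}
    next_id = g.n_vertices
    queue = [v for v in range(g.n_vertices) if alive[v] and len(children[v]) > 2]
    if queue:
        logger.warning("classical_stats: %d polytomies resolved with zero-length edges", len(queue))
    all_children = {v: children[v] for v in range(g.n_vertices) if alive[v]}
    all_elen = {v: elen[v] for v in range(g.n_vertices) if alive[v]}
    is_tip = {v: bool(g.is_tip[v]) for v in range(g.n_vertices) if alive[v]}
    work = list(all_children.keys())
    for v in work:
        while len(all_children[v]) > 2:
            c1 = all_children[v].pop()
            c2 = all_children[v].pop()
            nv = next_id
            next_id += 1
            all_children[nv] = [c1, c2]
            all_elen[nv] = 0.0
            is_tip[nv] = False
            all_children[v].append(nv)
    return all_children, all_elen, is_tip, root


def classical_stats(t) -> dict:
    """Classical (Group III) metrics; requires a rooted tree with >= 4 tips."""
    g = _TreeGraph(t)
    n = g.n_tips
    if n < 4:
        raise ValueError(f"classical statistics need >= 4 tips, got {n}")
    children, elen, is_tip, root = _binarized(g)

    # per-node tip counts, topological depths, max depth below, branch depths
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        stack.extend(children.get(v, []))
    depth_topo = {root: 0}
    depth_bl = {root: 0.0}
    for v in order:
        for c in children.get(v, []):
            depth_topo[c] = depth_topo[v] + 1
            depth_bl[c] = depth_bl[v] + elen.get(c, 0.0)
    tipcount = {}
    maxdepth_below = {}  # in edges, measured from the node
    for v in reversed(order):
        kids = children.get(v, [])
        if not kids:
            tipcount[v] = 1
            maxdepth_below[v] = 0
        else:
            tipcount[v] = sum(tipcount[c] for c in kids)
            maxdepth_below[v] = 1 + max(maxdepth_below[c] for c in kids)

    internal = [v for v in order if children.get(v)]
    colless = sum(abs(tipcount[children[v][0]] - tipcount[children[v][1]])
                  for v in internal if len(children[v]) == 2)
    colless_norm = colless / ((n - 1) * (n - 2) / 2.0)
    tips = [v for v in order if not children.get(v)]
    sackin_norm = sum(depth_topo[v] for v in tips) / n
    cherries = sum(1 for v in internal
                   if len(children[v]) == 2 and all(not children.get(c) for c in children[v]))
    cherries_norm = cherries / (n // 2)
    # Pybus–Harvey gamma from node times; the "present" is the mean tip depth
    present = float(np.mean([depth_bl[v] for v in tips]))
    s = sorted(depth_bl[v] for v in internal)  # n-1 speciation times, s[0]=0 at root
    gamma = _pybus_harvey_gamma(s, present, n)
    b_internal = sum(elen.get(v, 0.0) for v in internal if v != root)
    b_total = sum(elen.get(v, 0.0) for v in order if v != root)
    treeness = b_internal / b_total if b_total > 0 else 0.0
    b1 = sum(1.0 / maxdepth_below[v] for v in internal if v != root)
    p = np.array([2.0 ** (-depth_topo[v]) for v in tips])
    b2 = float(-(p * np.log(p)).sum())
    return {
        "colless_norm": float(colless_norm),
        "sackin_norm": float(sackin_norm),
        "cherries_norm": float(cherries_norm),
        "gamma_stat": float(gamma),
        "treeness": float(treeness),
        "B1": float(b1),
        "B2": b2,
        "max_depth_topo": float(max(depth_topo[v] for v in tips)),
    }


def _pybus_harvey_gamma(speciation_times, present: float, n: int) -> float:
    """Gamma statistic from sorted speciation (internal node) times.

    ``speciation_times`` has n-1 entries (root at time 0); the interval with
    k lineages runs from the (k-1)-th to the k-th speciation, the last one
    ending at ``present``.
    """
    s = list(speciation_times)
    if len(s) != n - 1:
        # defensive: polytomy resolution keeps n-1 internal nodes for binary trees
        s = (s + [present] * (n - 1))[: n - 1]
    times = s[1:] + [present]  # end of interval with k = 2..n lineages
    starts = s  # start of interval with k = 2..n lineages
    g = [max(e - b, 0.0) for b, e in zip(starts, times)]
    ks = list(range(2, n + 1))
    T = sum(k * gk for k, gk in zip(ks, g))
    if T <= 0:
        logger.warning("gamma_stat: zero total branching time; returning 0")
        return 0.0
    inner = 0.0
    cum = 0.0
    for i, (k, gk) in enumerate(zip(ks, g)):
        cum += k * gk
        if k <= n - 1:  # sum over i = 2..n-1
            inner += cum
    gamma = (inner / (n - 2) - T / 2.0) / (T * math.sqrt(1.0 / (12.0 * (n - 2))))
    return gamma


# ---------------------------------------------------------------------------
# Group IV


def tipdist_stats(t) -> dict:
    """Tip-distance (Group IV) metrics; requires >= 2 tips."""
    g = _TreeGraph(t)
    if g.n_tips < 2:
        raise ValueError("tip distance statistics need >= 2 tips")
    d = g.depths(topological=False)
    P = g.patristic_all()
    tips = np.flatnonzero(g.is_tip)
    TT = P[np.ix_(tips, tips)]
    iu = np.triu_indices(len(tips), k=1)
    pair = TT[iu]
    bl_total = float(g.edge_length[g.parent >= 0].sum())
    mean = float(pair.mean())
    if bl_total > 0:
        norm = mean / bl_total
    else:
        logger.warning("tipdist_stats: zero total branch length; tipDistNorm set to 0")
        norm = 0.0
    root_tip = d[tips]
    return {
        "tipDist_mean": mean,
        "tipDist_var": float(pair.var()),
        "tipDist_max": float(pair.max()),
        "tipDistNorm": float(norm),
        "tipRootPatr": float(root_tip.mean()),
        "tipRootPatr_var": float(root_tip.var()),
    }


# ---------------------------------------------------------------------------
# Group V


def powergraph_features(t) -> dict:
    """Powergraph (Group V) metrics; requires >= 3 tips."""
    g = _TreeGraph(t)
    if g.n_tips < 3:
        raise ValueError("powergraph features need >= 3 tips")
    A = g.adjacency(weighted=False).toarray()
    A2 = ((A + A @ A) > 0).astype(float)
    np.fill_diagonal(A2, 0.0)
    lam = np.linalg.eigvalsh(_laplacian(A2))
    return {"pg_lmax": float(lam[-1]), "pg_AC2": float(lam[1])}


# ---------------------------------------------------------------------------


def compute_features(t, tree_id=None, sample_id=None, replicate_id=None) -> TreeFeatureVector:
    """All 31 metrics for one tree (tips >= 4, deterministic)."""
    values = {}
    values.update(spectral_features(t))
    values.update(branch_stats(t))
    values.update(classical_stats(t))
    values.update(tipdist_stats(t))
    values.update(powergraph_features(t))
    return TreeFeatureVector(values=values, tree_id=tree_id, sample_id=sample_id,
                             replicate_id=replicate_id)


def features_table(trees, sample_ids, replicate_ids):
    """Feature DataFrame with ``sample_id, replicate_id`` + the 31 metrics."""
    import pandas as pd

    rows = []
    for t, sid, rid in zip(trees, sample_ids, replicate_ids):
        fv = compute_features(t, sample_id=sid, replicate_id=rid)
        rows.append({"sample_id": sid, "replicate_id": rid, **fv.values})
    return pd.DataFrame(rows, columns=["sample_id", "replicate_id"] + FEATURE_NAMES)
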