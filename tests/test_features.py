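"""The 31 tree-shape metrics: oracles, invariances, group structure."""

import dendropy
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from celltreeage.features import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    _laplacian,
    _TreeGraph,
    branch_stats,
    classical_stats,
    compute_features,
    features_table,
    powergraph_features,
    spectral_features,
    tipdist_stats,
)
from celltreeage.trees import CellTree
from conftest import random_ultrametric_tree


def scale_tree(t: CellTree, c: float) -> CellTree:
    t2 = CellTree.from_newick(t.as_newick())
    for e in t2.tree.edges():
        if e.length is not None:
            e.length = e.length * c
    return t2


class TestCatalog:
    def test_31_unique_names_in_five_groups(self):
        assert len(FEATURE_NAMES) == 31
        assert len(set(FEATURE_NAMES)) == 31
        counts = {g: sum(1 for v in FEATURE_GROUPS.values() if v == g)
                  for g in "I II III IV V".split()}
        assert counts == {"I": 8, "II": 7, "III": 8, "IV": 6, "V": 2}
        for named in ("tipDistNorm", "mMax_eigengap", "mMaxEigen", "AC_2", "tipRootPatr"):
            assert named in FEATURE_NAMES

    def test_all_finite_on_random_trees(self, rng):
        for n in (4, 7, 20):
            fv = compute_features(random_ultrametric_tree(n, rng))
            assert all(np.isfinite(v) for v in fv.values.values())

    def test_label_permutation_and_rotation_invariance(self, rng):
        t = random_ultrametric_tree(10, rng)
        fv1 = compute_features(t)
        # rotate children order by re-reading a ladderized copy
        t2 = CellTree.from_newick(t.as_newick())
        t2.tree.ladderize(ascending=False)
        fv2 = compute_features(t2)
        for k in FEATURE_NAMES:
            assert fv1.values[k] == pytest.approx(fv2.values[k], rel=1e-9), k

    def test_feature_table_shape(self, rng):
        trees = [random_ultrametric_tree(8, rng) for _ in range(5)]
        df = features_table(trees, ["s1"] * 5, list(range(5)))
        assert df.shape == (5, 33)
        assert list(df.columns[:2]) == ["sample_id", "replicate_id"]


class TestSpectral:
    def test_path_graph_algebraic_connectivity(self):
        """A 2-tip unit-branch tree is the path on 3 vertices with
        unweighted Laplacian eigenvalues {0, 1, 3}."""
        t = CellTree.from_newick("(A:1,B:1);")
        g = _TreeGraph(t)
        lam = np.linalg.eigvalsh(_laplacian(g.adjacency(weighted=False).toarray()))
        assert lam == pytest.approx([0.0, 1.0, 3.0], abs=1e-12)

    def test_requires_three_tips(self):
        with pytest.raises(ValueError):
            spectral_features(CellTree.from_newick("(A:1,B:1);"))

    def test_branch_scaling_behaviour(self, rng):
        t = random_ultrametric_tree(9, rng)
        c = 3.7
        f1, f2 = spectral_features(t), spectral_features(scale_tree(t, c))
        for k in ("mMaxEigen", "mMax_eigengap", "lmax_graph"):
            assert f2[k] == pytest.approx(c * f1[k], rel=1e-9)
        assert f2["AC_2"] == pytest.approx(f1["AC_2"], rel=1e-12)
        assert f2["eigengap_pos"] == f1["eigengap_pos"]

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        """Recompute every eigen metric from scratch with scipy primitives."""
        t = random_ultrametric_tree(16, rng)
        g = _TreeGraph(t)
        W = g.adjacency(weighted=True).toarray()
        A = g.adjacency(weighted=False).toarray()
        P = shortest_path(g.adjacency(weighted=True), directed=False)
        mgl = np.diag(P.sum(1)) - P
        lam = np.linalg.eigvalsh(mgl)
        desc = lam[::-1]
        gaps = desc[:-1] - desc[1:]
        f = spectral_features(t)
        assert f["mMaxEigen"] == pytest.approx(desc[0], abs=1e-8)
        assert f["mMax_eigengap"] == pytest.approx(gaps.max(), abs=1e-8)
        assert f["AC_2"] == pytest.approx(np.linalg.eigvalsh(np.diag(A.sum(1)) - A)[1], abs=1e-8)
        assert f["lmax_graph"] == pytest.approx(np.linalg.eigvalsh(np.diag(W.sum(1)) - W)[-1], abs=1e-8)
        p = np.clip(lam, 0, None)
        p = p / p.sum()
        ent = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert f["spec_entropy"] == pytest.approx(ent, abs=1e-8)


class TestBranchStats:
    def test_uniform_lengths_maximize_entropy(self):
        t = CellTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        f = branch_stats(t)
        assert f["bl_entropy"] == pytest.approx(np.log(6))
        assert f["bl_var"] == 0.0
        assert f["bl_total"] == 6.0

    def test_flat_loop_oracle(self, rng):
        t = random_ultrametric_tree(6, rng)  # 10 edges
        lengths = [e.length for e in t.tree.edges() if e.length is not None]
        internal = [e.length for e in t.tree.edges()
                    if e.length is not None and not e.head_node.is_leaf()]
        terminal = [e.length for e in t.tree.edges()
                    if e.length is not None and e.head_node.is_leaf()]
        b = np.array(lengths)
        f = branch_stats(t)
        assert f["bl_total"] == pytest.approx(b.sum())
        assert f["bl_mean"] == pytest.approx(b.mean())
        assert f["bl_median"] == pytest.approx(np.median(b))
        assert f["bl_var"] == pytest.approx(b.var())
        assert f["bl_max"] == pytest.approx(b.max())
        p = b / b.sum()
        assert f["bl_entropy"] == pytest.approx(-(p[p > 0] * np.log(p[p > 0])).sum())
        assert f["bl_int_ext_ratio"] == pytest.approx(sum(internal) / sum(terminal))


class TestClassical:
    def test_balanced_four_tips(self):
        t = CellTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        f = classical_stats(t)
        assert f["colless_norm"] == 0.0
        assert f["cherries_norm"] == 1.0  # 2 cherries / floor(4/2)
        assert f["sackin_norm"] == 2.0
        assert f["max_depth_topo"] == 2.0

    def test_caterpillar_four_tips(self):
        t = CellTree.from_newick("(((a:1,b:1):1,c:2):1,d:3);")
        f = classical_stats(t)
        # |1-3| + |1-2| + |1-1| = 3 over (n-1)(n-2)/2 = 3
        assert f["colless_norm"] == pytest.approx(1.0)
        assert f["cherries_norm"] == pytest.approx(0.5)
        assert f["sackin_norm"] == pytest.approx((3 + 3 + 2 + 1) / 4)
        # B1: internal non-root nodes at max tip depths 1 and 2 below
        assert f["B1"] == pytest.approx(1.0 + 0.5)
        p = np.array([1 / 8, 1 / 8, 1 / 4, 1 / 2])
        assert f["B2"] == pytest.approx(-(p * np.log(p)).sum())

    def test_requires_four_tips(self):
        with pytest.raises(ValueError):
            classical_stats(CellTree.from_newick("((a:1,b:1):1,c:2);"))

    def test_colless_and_sackin_match_dendropy(self, rng):
        for n in (5, 11, 24):
            t = random_ultrametric_tree(n, rng)
            dt = dendropy.Tree.get(data=t.as_newick(), schema="newick")
            f = classical_stats(t)
            raw_colless = dendropy.calculate.treemeasure.colless_tree_imbalance(
                dt, normalize=None)
            assert f["colless_norm"] == pytest.approx(
                raw_colless / ((n - 1) * (n - 2) / 2))
            raw_sackin = dendropy.calculate.treemeasure.sackin_index(dt, normalize=None)
            assert f["sackin_norm"] == pytest.approx(raw_sackin / n)

    def test_gamma_matches_dendropy(self, rng):
        for n in (6, 15):
            t = random_ultrametric_tree(n, rng)
            dt = dendropy.Tree.get(data=t.as_newick(), schema="newick")
            expected = dendropy.calculate.treemeasure.pybus_harvey_gamma(dt)
            assert classical_stats(t)["gamma_stat"] == pytest.approx(expected, rel=1e-6)

    def test_treeness_is_internal_fraction(self):
        t = CellTree.from_newick("((a:2,b:2):1,(c:1,d:1):2);")
        f = classical_stats(t)
        assert f["treeness"] == pytest.approx(3 / 9)


class TestTipDist:
    def test_ultrametric_height_and_zero_variance(self, rng):
        t = random_ultrametric_tree(10, rng)
        f = tipdist_stats(t)
        height = max(t.root_to_tip_depths().values())
        assert f["tipRootPatr"] == pytest.approx(height, rel=1e-9)
        assert f["tipRootPatr_var"] == pytest.approx(0.0, abs=1e-15)

    def test_two_tip_hand_computation(self):
        t = CellTree.from_newick("(A:0.2,B:0.2);")
        f = tipdist_stats(t)
        assert f["tipDist_mean"] == pytest.approx(0.4)
        assert f["tipDist_max"] == pytest.approx(0.4)
        assert f["tipDistNorm"] == pytest.approx(1.0)
        assert f["tipDist_var"] == 0.0

    def test_matches_path_sum_oracle(self, rng):
        t = random_ultrametric_tree(12, rng)
        g = _TreeGraph(t)
        P = shortest_path(g.adjacency(weighted=True), directed=False)
        tips = np.flatnonzero(g.is_tip)
        TT = P[np.ix_(tips, tips)]
        iu = np.triu_indices(len(tips), 1)
        f = tipdist_stats(t)
        assert f["tipDist_mean"] == pytest.approx(TT[iu].mean())
        assert f["tipDist_var"] == pytest.approx(TT[iu].var())
        assert f["tipDist_max"] == pytest.approx(TT[iu].max())
        root = g.root
        rt = P[root, tips]
        assert f["tipRootPatr"] == pytest.approx(rt.mean())
        assert f["tipRootPatr_var"] == pytest.approx(rt.var())


class TestAgeSignal:
    def test_a_tip_distance_metric_tracks_age(self, default_age_cohort):
        """The premise the age model exploits: on a default-configuration
        cohort, at least one tip-distance (Group IV) metric correlates
        strongly with age on the true trees."""
        ages, truths = default_age_cohort
        names = [k for k, g in FEATURE_GROUPS.items() if g == "IV"]
        vals = {k: [] for k in names}
        for t in truths:
            f = tipdist_stats(t.true_tree)
            for k in names:
                vals[k].append(f[k])
        best = max(abs(np.corrcoef(v, ages)[0, 1])
                   for v in vals.values() if np.std(v) > 0)
        assert best >= 0.5


class TestPowergraph:
    def test_path_graph_square_is_triangle(self):
        """Squaring the path on 3 vertices gives K3: eigenvalues {0, 3, 3}."""
        t = CellTree.from_newick("(A:1,B:1);")
        g = _TreeGraph(t)
        A = g.adjacency(weighted=False).toarray()
        A2 = ((A + A @ A) > 0).astype(float)
        np.fill_diagonal(A2, 0)
        lam = np.linalg.eigvalsh(_laplacian(A2))
        assert lam == pytest.approx([0.0, 3.0, 3.0], abs=1e-12)

    def test_square_never_less_connected(self, rng):
        for k in range(25):
            t = random_ultrametric_tree(int(rng.integers(4, 16)), rng)
            f = compute_features(t)
            assert f.values["pg_AC2"] >= f.values["AC_2"] - 1e-12
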