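import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import picrisk as pk


def brownian_covariance(tree: pk.Phylogeny) -> np.ndarray:
    """Oracle: tip covariance under Brownian motion = shared root-to-MRCA
    path length, built by explicit parent-pointer traversal."""
    depth, anc = {}, {}
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            depth[id(nd)], anc[id(nd)] = 0.0, [nd]
        else:
            depth[id(nd)] = depth[id(nd.parent_node)] + nd.edge.length
            anc[id(nd)] = anc[id(nd.parent_node)] + [nd]
    tips = tree.tip_labels
    leaves = {lf.taxon.label: lf for lf in tree.tree.leaf_node_iter()}
    C = np.zeros((len(tips), len(tips)))
    for i, a in enumerate(tips):
        for j, b in enumerate(tips):
            sa = {id(x) for x in anc[id(leaves[a])]}
            shared = [x for x in anc[id(leaves[b])] if id(x) in sa]
            C[i, j] = depth[id(shared[-1])]
    return C


class TestRecursion:
    def test_single_cherry(self):
        cs = pk.compute_pics(pk.parse_tree("(A:1,B:1);"), {"A": 3, "B": 1})
        assert len(cs) == 1
        assert cs.standardized[0] == pytest.approx(2 / math.sqrt(2))

    def test_constant_trait_gives_zero_contrasts(self):
        tree = pk.simulate_tree(12, "yule", seed=9)
        cs = pk.compute_pics(tree, {t: 7.7 for t in tree.tip_labels})
        assert np.allclose(cs.raw, 0.0)

    def test_three_tip_hand_execution(self, cherry_plus_outgroup):
        cs = pk.compute_pics(cherry_plus_outgroup, {"A": 2, "B": 0, "C": 1})
        tab = cs.table.set_index("node")
        assert tab.loc["A|B", "standardized"] == pytest.approx(2 / math.sqrt(2))
        # ancestral value of (A,B) is 1 and its branch is adjusted to
        # 1 + (1*1)/(1+1) = 1.5, so the root contrast is (1-1)/sqrt(2.5) = 0
        assert tab.loc["A|C", "variance"] == pytest.approx(2.5)
        assert tab.loc["A|C", "standardized"] == pytest.approx(0.0)

    def test_missing_tip_values_listed(self, cherry_plus_outgroup):
        with pytest.raises(pk.TreeError, match=r"\['C'\]"):
            pk.compute_pics(cherry_plus_outgroup, {"A": 1, "B": 2})

    def test_nonpositive_branch_length_rejected(self):
        tree = pk.parse_tree("((A:1,B:0):1,C:1);")
        with pytest.raises(pk.TreeError, match="positive"):
            pk.compute_pics(tree, {"A": 1, "B": 2, "C": 3})

    def test_polytomy_rejected(self):
        tree = pk.parse_tree("((A:1,B:1,C:1):1,D:1);")
        with pytest.raises(pk.TreeError, match="polytom"):
            pk.compute_pics(tree, {"A": 1, "B": 2, "C": 3, "D": 4})

    def test_standardized_is_raw_over_sqrt_variance(self):
        tree = pk.simulate_tree(10, "yule", seed=4)
        vals = dict(zip(tree.tip_labels,
                        np.random.default_rng(0).standard_normal(10)))
        cs = pk.compute_pics(tree, vals)
        assert np.allclose(
            cs.standardized, cs.raw / np.sqrt(cs.table["variance"]))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(n=st.integers(2, 25), seed=st.integers(0, 10_000),
       model=st.sampled_from(["yule", "balanced"]))
def test_contrast_count_is_tips_minus_one(n, seed, model):
    tree = pk.simulate_tree(n, model, seed=seed)
    vals = dict(zip(tree.tip_labels,
                    np.random.default_rng(seed).standard_normal(n)))
    assert len(pk.compute_pics(tree, vals)) == n - 1


def test_subtraction_order_flip_leaves_slope_unchanged():
    """Relabeling the cherry flips that node's x and y contrasts together,
    so the through-origin slope on raw contrasts is unchanged."""
    t1 = pk.parse_tree("((A:1,B:1):1,C:1);")
    t2 = pk.parse_tree("((B:1,A:1):1,C:1);")  # same tree, order irrelevant
    x = {"A": 2.0, "B": -1.0, "C": 0.5}
    y = {"A": 1.5, "B": 0.5, "C": -1.0}
    cx1, cy1 = pk.compute_pics(t1, x).raw, pk.compute_pics(t1, y).raw
    # manually flip the cherry contrast in both traits
    cx2, cy2 = cx1.copy(), cy1.copy()
    cx2[0], cy2[0] = -cx2[0], -cy2[0]
    slope1 = (cx1 @ cy1) / (cx1 @ cx1)
    slope2 = (cx2 @ cy2) / (cx2 @ cx2)
    assert slope1 == pytest.approx(slope2, rel=1e-12)
    # and the deterministic child ordering ignores input rotation
    assert np.allclose(cx1, pk.compute_pics(t2, x).raw)


def test_matches_dendropy_reference():
    """Independent oracle: dendropy's contrast implementation (its node
    ordering differs, so compare the multisets of |contrast| and variance)."""
    import dendropy
    from dendropy.model.continuous import PhylogeneticIndependentContrasts

    nwk = "(((A:1,B:2):1.5,C:0.8):1,(D:1.2,E:0.7):2);"
    vals = {"A": 1.3, "B": -0.4, "C": 2.2, "D": 0.5, "E": -1.1}
    mine = pk.compute_pics(pk.parse_tree(nwk), vals)

    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree.get(data=nwk, schema="newick", taxon_namespace=taxa)
    chars = dendropy.ContinuousCharacterMatrix.from_dict(
        {k: [v] for k, v in vals.items()}, taxon_namespace=taxa)
    ref = PhylogeneticIndependentContrasts(tree=dtree, char_matrix=chars)
    ctree = ref.contrasts_tree(character_index=0,
                               annotate_pic_statistics=True)
    ref_std = sorted(abs(nd.pic_contrast_standardized)
                     for nd in ctree.postorder_internal_node_iter())
    ref_var = sorted(nd.pic_contrast_variance
                     for nd in ctree.postorder_internal_node_iter())
    assert np.allclose(sorted(abs(mine.standardized)), ref_std)
    assert np.allclose(sorted(mine.table["variance"]), ref_var)


def test_pic_slope_equals_gls_slope(rng):
    """The through-origin regression on standardized contrasts equals the
    GLS slope under the Brownian tip covariance, for every tree tried."""
    for _ in range(15):
        n = int(rng.integers(3, 9))
        tree = pk.simulate_tree(n, "yule", seed=rng)
        x = dict(zip(tree.tip_labels, rng.standard_normal(n)))
        y = dict(zip(tree.tip_labels, rng.standard_normal(n)))
        cx = pk.compute_pics(tree, x).standardized
        cy = pk.compute_pics(tree, y).standardized
        pic_slope = (cx @ cy) / (cx @ cx)
        C = brownian_covariance(tree)
        Ci = np.linalg.inv(C)
        X = np.column_stack([np.ones(n), [x[t] for t in tree.tip_labels]])
        yv = np.array([y[t] for t in tree.tip_labels])
        gls = np.linalg.solve(X.T @ Ci @ X, X.T @ Ci @ yv)
        assert pic_slope == pytest.approx(gls[1], rel=1e-10)


def test_root_state_does_not_affect_contrasts():
    tree = pk.simulate_tree(8, "yule", seed=6)
    vals = dict(zip(tree.tip_labels, range(8)))
    shifted = {k: v + 100.0 for k, v in vals.items()}
    assert np.allclose(pk.compute_pics(tree, vals).standardized,
                       pk.compute_pics(tree, shifted).standardized)


class TestTransformer:
    def test_matches_function_and_aligns_nodes(self, cherry_plus_outgroup):
        X = pd.DataFrame({"z": [2.0, 0.0, 1.0], "w": [1.0, 1.0, 4.0]},
                         index=["A", "B", "C"])
        tr = pk.IndependentContrasts(cherry_plus_outgroup)
        out = tr.fit_transform(X)
        assert list(out.index) == ["A|B", "A|C"]
        assert np.allclose(
            out["w"],
            pk.compute_pics(cherry_plus_outgroup, X["w"].to_dict()).standardized)

    def test_missing_rows_error(self, cherry_plus_outgroup):
        X = pd.DataFrame({"z": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(pk.TreeError, match="C"):
            pk.IndependentContrasts(cherry_plus_outgroup).fit(X)

    def test_sklearn_params_roundtrip(self, cherry_plus_outgroup):
        from sklearn.base import clone
        tr = pk.IndependentContrasts(cherry_plus_outgroup, scaled=False)
        assert clone(tr).get_params()["scaled"] is False
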