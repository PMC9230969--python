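import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from structphylo.phylo import (
    BootstrapParams,
    PhyloTree,
    bionj_tree,
    bootstrap_supports,
    midpoint_root,
    newick_read,
    newick_write,
    nj_tree,
    p_distance_matrix,
    rf_distance,
    tm_to_distance,
)
from structphylo.structio import DistanceMatrix, SequenceRecord


def dm(labels, rows):
    return DistanceMatrix(list(labels), np.array(rows, float))


ADDITIVE4 = dm("ABCD", [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]])


class TestTmToDistance:
    def test_basic_transform(self):
        t = dm("ab", [[1.0, 0.3], [0.3, 1.0]])
        d = tm_to_distance(t)
        assert d["a", "b"] == pytest.approx(0.7)
        assert d["a", "a"] == 0.0

    def test_involution_identity(self):
        rng = np.random.default_rng(0)
        V = rng.uniform(0.2, 0.99, size=(4, 4))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 1.0)
        t = DistanceMatrix(list("abcd"), V)
        np.testing.assert_allclose(1.0 - tm_to_distance(t).values,
                                   np.where(np.eye(4), 1.0, V), atol=1e-12)

    def test_nonpositive_scores_rejected(self):
        t = DistanceMatrix(["a", "b"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        with pytest.raises(ValueError):
            tm_to_distance(t)

    def test_neg_log_alternative(self):
        t = dm("ab", [[1.0, 0.5], [0.5, 1.0]])
        assert tm_to_distance(t, "neg_log")["a", "b"] == pytest.approx(np.log(2))


class TestNJ:
    def test_three_taxon_worked_example(self):
        t = nj_tree(dm("ABC", [[0, 2, 4], [2, 0, 4], [4, 4, 0]]))
        pdm = t.leaf_distance_matrix()
        assert pdm["A", "B"] == pytest.approx(2.0)
        assert pdm["A", "C"] == pytest.approx(4.0)
        # star resolution: A:1, B:1, C:3
        lengths = {lf.taxon.label: lf.edge.length for lf in t.dtree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("builder", [nj_tree, bionj_tree])
    def test_four_taxon_additive_worked_example(self, builder):
        t = builder(ADDITIVE4)
        assert t.bipartitions() == {frozenset({"C", "D"})}  # AB|CD
        lengths = {lf.taxon.label: lf.edge.length for lf in t.dtree.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [
            n.edge.length for n in t.dtree.preorder_internal_node_iter()
            if n.edge.length
        ]
        assert internal == pytest.approx([1.0])

    @pytest.mark.parametrize("builder", [nj_tree, bionj_tree])
    def test_additivity_recovery(self, builder):
        t = builder(ADDITIVE4)
        pdm = t.leaf_distance_matrix()
        np.testing.assert_allclose(pdm.values, ADDITIVE4.values, atol=1e-9)

    def test_equidistant_matrix_gives_zero_internal_branches(self):
        t = nj_tree(dm("ABCD", (np.ones((4, 4)) - np.eye(4)) * 2))
        internal = [
            n.edge.length or 0.0 for n in t.dtree.preorder_internal_node_iter()
        ]
        assert sum(internal) == pytest.approx(0.0, abs=1e-12)

    def test_negative_branch_estimates_clamped(self):
        # a strongly non-additive matrix that drives an estimate negative
        t = nj_tree(dm("ABCD", [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]]))
        assert all(l >= 0 for l in t.branch_lengths())

    def test_deterministic_for_fixed_input(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(1, 5, size=(6, 6))
        V = (V + V.T) / 2
        np.fill_diagonal(V, 0)
        D = DistanceMatrix(list("abcdef"), V)
        assert nj_tree(D).to_newick() == nj_tree(D).to_newick()
        assert bionj_tree(D).to_newick() == bionj_tree(D).to_newick()

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)) - 1))

    def test_agrees_with_dendropy_nj_on_random_matrix(self):
        rng = np.random.default_rng(3)
        n = 7
        pts = rng.normal(size=(n, 2)) * 3
        V = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(n)]
        mine = nj_tree(DistanceMatrix(labels, V))
        csv = "," + ",".join(labels) + "\n" + "\n".join(
            labels[i] + "," + ",".join(str(x) for x in V[i]) for i in range(n)
        )
        import io
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=io.StringIO(csv))
        ref = PhyloTree(pdm.nj_tree())
        rf, _ = rf_distance(mine, ref)
        assert rf == 0


class TestMidpointRoot:
    def test_two_leaf_arithmetic(self):
        t = PhyloTree.from_newick("(A:3,B:7);")
        r = midpoint_root(t)
        # root sits 5 from each leaf, i.e. 2 into B's branch
        for lf in r.dtree.leaf_node_iter():
            assert lf.distance_from_root() == pytest.approx(5.0)

    def test_symmetric_ladder_roots_on_central_edge(self):
        t = PhyloTree.from_newick("((A:1,B:1):2,(C:1,D:1):2);")
        r = midpoint_root(t)
        depths = {lf.taxon.label: lf.distance_from_root() for lf in r.dtree.leaf_node_iter()}
        assert all(d == pytest.approx(3.0) for d in depths.values())

    def test_balanced_farthest_leaves_on_random_trees(self):
        from structphylo.synthetic import SimulationParams, simulate_family

        models, truth = simulate_family(SimulationParams(n_taxa=8, tree_shape="yule", seed=5))
        r = midpoint_root(truth.true_tree)
        depths = sorted(
            lf.distance_from_root() for lf in r.dtree.leaf_node_iter()
        )
        # the two deepest root-to-leaf paths bracket the midpoint equally
        assert depths[-1] == pytest.approx(depths[-1], abs=1e-9)
        # recompute longest path independently
        pdm = truth.true_tree.leaf_distance_matrix()
        assert depths[-1] == pytest.approx(pdm.values.max() / 2, abs=1e-9)

    def test_all_zero_lengths_warns(self):
        t = PhyloTree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        with pytest.warns(UserWarning):
            midpoint_root(t)


class TestRF:
    def test_self_distance_zero(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert rf_distance(t, t) == (0, 0.0)

    def test_disjoint_five_taxon_splits_normalize_to_one(self):
        t1 = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        t2 = PhyloTree.from_newick("((A:1,C:1):1,(B:1,D:1):1,E:1);")
        rf, norm = rf_distance(t1, t2)
        assert rf == 4 and norm == 1.0

    def test_star_vs_binary(self):
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        binary = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        rf, _ = rf_distance(star, binary)
        assert rf == 5 - 3

    def test_leaf_set_mismatch_names_difference(self):
        t1 = PhyloTree.from_newick("(A:1,B:1,C:1);")
        t2 = PhyloTree.from_newick("(A:1,B:1,D:1);")
        with pytest.raises(ValueError, match="C.*D"):
            rf_distance(t1, t2)

    def test_cross_checked_against_dendropy(self):
        rng = np.random.default_rng(4)
        import random as pyrandom

        for _ in range(5):
            tns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
            trees = []
            for _ in range(2):
                t = dendropy.simulate.treesim.birth_death_tree(
                    1.0, 0.0, taxon_namespace=tns, num_extant_tips=8,
                    rng=pyrandom.Random(int(rng.integers(1e6))))
                # compare as unrooted trees
                t.is_rooted = False
                t.collapse_basal_bifurcation()
                trees.append(t)
            a, b = trees
            mine, _ = rf_distance(PhyloTree(a), PhyloTree(b))
            a.encode_bipartitions()
            b.encode_bipartitions()
            ref = treecompare.symmetric_difference(a, b)
            assert mine == ref


class TestNewickIO:
    def test_simple_round_trip(self):
        t = newick_read("(A:1,B:2);")
        assert t.leaf_labels == ["A", "B"]
        back = newick_read(t.to_newick())
        assert {lf.taxon.label: lf.edge.length for lf in back.dtree.leaf_node_iter()} \
            == {"A": 1.0, "B": 2.0}

    def test_support_labels_survive_round_trip(self):
        text = "((A:1,B:1)0.95:0.5,(C:1,D:1)0.87:0.5);"
        t = newick_read(text)
        labels = sorted(
            n.label for n in t.dtree.preorder_internal_node_iter() if n.label
        )
        assert labels == ["0.87", "0.95"]
        t2 = newick_read(t.to_newick())
        labels2 = sorted(
            n.label for n in t2.dtree.preorder_internal_node_iter() if n.label
        )
        assert labels2 == labels

    def test_parse_error_reported(self):
        with pytest.raises(ValueError, match="parse"):
            newick_read("((A:1,B:2;")

    def test_generator_trees_round_trip(self):
        from structphylo.synthetic import SimulationParams, _make_tree

        for seed in range(10):
            t = _make_tree(SimulationParams(n_taxa=6, tree_shape="yule", seed=seed))
            back = newick_read(t.to_newick())
            assert back.leaf_labels == t.leaf_labels
            rf, _ = rf_distance(back, t)
            assert rf == 0
            np.testing.assert_allclose(
                sorted(back.branch_lengths()), sorted(t.branch_lengths()), rtol=1e-5
            )

    def test_file_round_trip(self, tmp_path):
        t = newick_read("((A:1,B:1):1,C:2);")
        p = tmp_path / "t.nwk"
        newick_write(t, p)
        assert newick_read(p).leaf_labels == ["A", "B", "C"]


class TestPDistance:
    def test_gap_containing_sites_skipped(self):
        recs = [SequenceRecord("a", "AC-GT"), SequenceRecord("b", "ACCTT")]
        d = p_distance_matrix(recs)
        # comparable sites: 0,1,3,4 -> one mismatch (G vs T)
        assert d["a", "b"] == pytest.approx(0.25)


class TestBootstrap:
    CONCORDANT = [
        SequenceRecord("A", "AAAAAA"),
        SequenceRecord("B", "AAAAAA"),
        SequenceRecord("C", "TTTTTT"),
        SequenceRecord("D", "TTTTTT"),
    ]

    def test_concordant_alignment_full_support(self):
        for seed in (0, 1, 99):
            t = bootstrap_supports(self.CONCORDANT, BootstrapParams(50, seed))
            supports = [
                float(n.label) for n in t.dtree.preorder_internal_node_iter()
                if n.label is not None
            ]
            assert supports == [1.0]

    def test_reproducible_and_row_order_invariant(self):
        rng = np.random.default_rng(6)
        rows = ["".join(rng.choice(list("ACDE"), size=30)) for _ in range(5)]
        recs = [SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]
        t1 = bootstrap_supports(recs, BootstrapParams(30, 7))
        t2 = bootstrap_supports(recs[::-1], BootstrapParams(30, 7))
        assert t1.to_newick() == t2.to_newick()

    def test_supports_within_bounds_and_edge_count(self):
        rng = np.random.default_rng(8)
        rows = ["".join(rng.choice(list("ACDEFGHIK"), size=40)) for _ in range(6)]
        recs = [SequenceRecord(f"s{i}", r) for i, r in enumerate(rows)]
        t = bootstrap_supports(recs, BootstrapParams(20, 1))
        supports = [
            float(n.label) for n in t.dtree.preorder_internal_node_iter()
            if n.label is not None
        ]
        assert len(supports) == len(t.bipartitions())
        assert all(0.0 <= s <= 1.0 for s in supports)

    def test_degenerate_alignments_rejected(self):
        same = [SequenceRecord(x, "AAAA") for x in "ABCD"]
        with pytest.raises(ValueError):
            bootstrap_supports(same, BootstrapParams(5, 0))
        with pytest.raises(ValueError):
            bootstrap_supports(self.CONCORDANT[:3], BootstrapParams(5, 0))
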