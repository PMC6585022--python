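import math

import numpy as np
import pytest

import oracles
from conftest import random_additive_matrix
from paralogon2r import msa, trees
from paralogon2r.trees import (
    DistanceMatrix,
    TreeInferenceError,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    poisson_distance_matrix,
    root_tree,
    tree_splits,
)


def _aln(pairs):
    text = "".join(f">{h}\n{s}\n" for h, s in pairs)
    return msa.read_alignment(text)


class TestDistances:
    def test_p_distance_values(self):
        aln = _aln([("Hsap|a", "ACDE"), ("Hsap|b", "ACDE"), ("Hsap|c", "ACDF")])
        dm = p_distance_matrix(aln)
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == pytest.approx(0.25)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_poisson_values(self):
        aln = _aln([("Hsap|a", "ACDE"), ("Hsap|b", "ACDF")])
        dm = poisson_distance_matrix(aln)
        assert dm.values[0, 1] == pytest.approx(-math.log(0.75))

    def test_poisson_saturation_names_pair(self):
        aln = _aln([("Hsap|a", "AC"), ("Hsap|b", "DE")])
        with pytest.raises(TreeInferenceError, match=r"Hsap\|a.*Hsap\|b"):
            poisson_distance_matrix(aln)

    def test_matrix_validation(self):
        with pytest.raises(TreeInferenceError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_recovers_known_quartet(self):
        d = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], float
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert tree_splits(t) == {frozenset({"A", "B"})}
        # internal edge of the generating tree has length 2
        ab = [n for n in t.preorder_node_iter() if not n.is_leaf() and n.parent_node]
        assert ab[0].edge.length == pytest.approx(2.0)

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_tree(DistanceMatrix(list("ABC"), d))
        lengths = {lf.taxon.label: lf.edge.length for lf in t.leaf_node_iter()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_tied_q_joins_lexicographically_smallest(self):
        d = np.ones((4, 4)) - np.eye(4)
        t = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert tree_splits(t) == {frozenset({"A", "B"})}

    def test_too_few_taxa(self):
        with pytest.raises(TreeInferenceError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_negative_lengths_clamped(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            d, _ = random_additive_matrix(rng, n)
            d = d + rng.normal(0, 0.05, d.shape)
            d = np.triu(d, 1)
            d = d + d.T
            np.fill_diagonal(d, 0.0)
            d = np.abs(d)
            t = nj_tree(DistanceMatrix([str(i) for i in range(n)], d))
            assert all(
                (nd.edge.length or 0) >= 0
                for nd in t.preorder_node_iter()
                if nd.parent_node
            )

    def test_recovers_random_additive_topologies(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(4, 7))
            d, true_splits = random_additive_matrix(rng, n)
            t = nj_tree(DistanceMatrix([str(i) for i in range(n)], d))
            assert tree_splits(t) == true_splits

    def test_agrees_with_skbio_on_additive_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(23)
        for _ in range(5):
            n = 6
            d, _ = random_additive_matrix(rng, n)
            labels = [str(i) for i in range(n)]
            ours = tree_splits(nj_tree(DistanceMatrix(labels, d)))
            sk = sk_nj(SkDM(d, labels))
            theirs = set()
            all_leaves = frozenset(labels)
            for node in sk.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= n - 2:
                    comp = all_leaves - side
                    theirs.add(min(side, comp, key=lambda s: (len(s), sorted(s))))
            assert ours == theirs


class TestBootstrap:
    CLEAN = [
        ("Hsap|a", "ACDEFGHIKL" * 10),
        ("Hsap|b", "ACDEFGHIKL" * 10),
        ("Mmus|a", "LKIHGFEDCA" * 10),
        ("Mmus|b", "LKIHGFEDCA" * 10),
    ]

    def test_clean_signal_full_support(self):
        t = bootstrap_support(_aln(self.CLEAN), B=100, seed=1)
        assert t.split_support[frozenset({"Hsap|a", "Hsap|b"})] == 100.0

    def test_same_seed_identical(self):
        a = bootstrap_support(_aln(self.CLEAN), B=50, seed=3)
        b = bootstrap_support(_aln(self.CLEAN), B=50, seed=3)
        assert a.split_support == b.split_support

    def test_supports_bounded_and_leaf_order_invariant(self):
        # unambiguous two-cluster signal: leaf reordering must not change
        # the annotated splits or their supports
        t = bootstrap_support(_aln(self.CLEAN), B=50, seed=9)
        assert all(0 <= v <= 100 for v in t.split_support.values())
        t2 = bootstrap_support(_aln(self.CLEAN[::-1]), B=50, seed=9)
        assert t.split_support == t2.split_support

    def test_supports_bounded_on_noisy_data(self):
        rng = np.random.default_rng(2)
        rows = [
            (f"Hsap|g{i}", "".join(rng.choice(list("ACDEFGHIKL"), 60)))
            for i in range(5)
        ]
        t = bootstrap_support(_aln(rows), B=50, seed=9)
        assert all(0 <= v <= 100 for v in t.split_support.values())


class TestRooting:
    def test_outgroup_rooting(self):
        aln = _aln(
            [
                ("Hsap|a", "AAAAAAAAAA"),
                ("Hsap|b", "AAAAAAAAAC"),
                ("Dmel|c", "CCCCCCCCCC"),
            ]
        )
        t = nj_tree(p_distance_matrix(aln))
        r = root_tree(t, ["Dmel|c"])
        kids = r.seed_node.child_nodes()
        labels = [
            frozenset(lf.taxon.label for lf in k.leaf_iter()) for k in kids
        ]
        assert frozenset({"Dmel|c"}) in labels

    def test_subfamily_rooting(self):
        # two subfamilies; one serves to root the other
        aln = _aln(
            [
                ("Hsap|s1a", "AAAAAAAAAA"),
                ("Mmus|s1b", "AAAAAAAAAC"),
                ("Hsap|s2a", "GGGGGGGGGG"),
                ("Mmus|s2b", "GGGGGGGGGC"),
            ]
        )
        t = nj_tree(p_distance_matrix(aln))
        r = root_tree(t, ["Hsap|s2a", "Mmus|s2b"])
        sides = [
            frozenset(lf.taxon.label for lf in k.leaf_iter())
            for k in r.seed_node.child_nodes()
        ]
        assert frozenset({"Hsap|s2a", "Mmus|s2b"}) in sides

    def test_outgroup_cannot_be_all(self):
        aln = _aln([("Hsap|a", "AAAA"), ("Hsap|b", "AAAC"), ("Dmel|c", "CCCC")])
        t = nj_tree(p_distance_matrix(aln))
        with pytest.raises(TreeInferenceError):
            root_tree(t, ["Hsap|a", "Hsap|b", "Dmel|c"])

    def test_nonmonophyletic_outgroup_warns(self):
        aln = _aln(
            [
                ("Hsap|a", "AAAAAAAAAA"),
                ("Dmel|b", "AAAAAAAAAC"),
                ("Hsap|c", "GGGGGGGGGG"),
                ("Dmel|d", "GGGGGGGGGC"),
            ]
        )
        t = nj_tree(p_distance_matrix(aln))
        with pytest.warns(UserWarning, match="monophyletic"):
            root_tree(t, ["Dmel|b", "Dmel|d"])

    def test_unroot_round_trip_preserves_splits(self):
        rng = np.random.default_rng(4)
        d, true_splits = random_additive_matrix(rng, 6)
        labels = [f"Hsap|g{i}" for i in range(6)]
        renamed = {
            frozenset(f"Hsap|g{x}" for x in s) for s in true_splits
        }
        t = nj_tree(DistanceMatrix(labels, d))
        r = root_tree(t, [labels[0]])
        # splits of the rooted tree, viewed unrooted, match the original
        all_leaves = frozenset(labels)
        back = set()
        for node in r.preorder_node_iter():
            if node is r.seed_node or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 2 <= len(side) <= len(all_leaves) - 2:
                comp = all_leaves - side
                back.add(min(side, comp, key=lambda s: (len(s), sorted(s))))
        canon = {
            min(s, all_leaves - s, key=lambda x: (len(x), sorted(x)))
            for s in renamed
        }
        assert back == canon


class TestDiscordantLeaves:
    def test_concordant_tree_clean(self, ref):
        import dendropy

        nwk = "((Hsap|a,Mmus|a),Ggal|a);"
        t = dendropy.Tree.get(
            data=nwk, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        t.is_rooted = True
        assert trees.flag_discordant_leaves(t, ref) == []

    def test_misplaced_fly_flagged(self, ref):
        import dendropy

        nwk = "((Hsap|a1,(Dmel|x,Mmus|a2)),(Hsap|b1,Mmus|b2));"
        t = dendropy.Tree.get(
            data=nwk, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        t.is_rooted = True
        assert trees.flag_discordant_leaves(t, ref) == ["Dmel|x"]

    def test_single_species_tree_clean(self, ref):
        import dendropy

        nwk = "((Hsap|a,Hsap|b),Hsap|c);"
        t = dendropy.Tree.get(
            data=nwk, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        t.is_rooted = True
        assert trees.flag_discordant_leaves(t, ref) == []
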