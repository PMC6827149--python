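"""K2P distances, neighbor joining, bootstrap, rooting, Newick IO."""

import math

import numpy as np
import pytest

from dloopphylo import phylo
from oracles import random_additive_tree


class TestK2P:
    def test_identical(self):
        res = phylo.k2p_distance("ACGT", "ACGT")
        assert res == (0.0, 0.0, 0.0)

    def test_known_value(self):
        # 20 sites: 2 transitions, 1 transversion -> P=0.1, Q=0.05;
        # d = -1/2 ln(0.75) - 1/4 ln(0.9) = 0.17018117...
        a = "A" * 20
        b = "G" * 2 + "C" * 1 + "A" * 17
        res = phylo.k2p_distance(a, b)
        assert res.p == pytest.approx(0.1)
        assert res.q == pytest.approx(0.05)
        assert res.d == pytest.approx(0.1701811651, abs=1e-9)

    def test_saturation_raises(self):
        a = "A" * 10
        b = "G" * 5 + "A" * 5  # P = 0.5, Q = 0: 1 - 2P - Q = 0
        with pytest.raises(phylo.SaturatedPairError):
            phylo.k2p_distance(a, b)

    def test_no_comparable_sites(self):
        with pytest.raises(ValueError, match="comparable"):
            phylo.k2p_distance("NNNN", "ACGT")

    def test_symmetry_and_lower_bound(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            L = 100
            a = "".join(rng.choice(list("ACGT"), L))
            b = list(a)
            for _ in range(rng.integers(0, 12)):
                i = rng.integers(L)
                b[i] = "ACGT"[rng.integers(4)]
            b = "".join(b)
            try:
                d_ab = phylo.k2p_distance(a, b)
                d_ba = phylo.k2p_distance(b, a)
            except phylo.SaturatedPairError:
                continue
            assert d_ab.d == pytest.approx(d_ba.d)
            # Jensen: the corrected distance dominates the raw proportion
            assert d_ab.d >= d_ab.p + d_ab.q - 1e-12

    def test_small_distance_limit(self):
        # d -> P + Q as divergence vanishes
        a = "A" * 1000
        b = "G" + "A" * 999
        res = phylo.k2p_distance(a, b)
        assert res.d == pytest.approx(res.p + res.q, abs=1e-3)


class TestNeighborJoining:
    def test_recovers_additive_four_taxon_tree(self):
        # distances from ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree, clamped = phylo.neighbor_joining(d, ids)
        assert not clamped
        paths = phylo.leaf_distances(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                key = tuple(sorted((ids[i], ids[j])))
                assert paths[key] == pytest.approx(d[i, j], abs=1e-9)
        assert phylo.bipartitions(tree) == {frozenset({"A", "B"})}

    def test_three_taxa_closed_form(self):
        ids = ["A", "B", "C"]
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree, _ = phylo.neighbor_joining(d, ids)
        lengths = {n.name: n.length for n in tree.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phylo.neighbor_joining(np.zeros((2, 2)), ["A", "B"])

    def test_recovers_random_additive_trees(self):
        # 50 random binary trees, 5-8 taxa: topology and every
        # leaf-to-leaf path length must be reproduced exactly
        rng = np.random.default_rng(41)
        for _ in range(50):
            n = int(rng.integers(5, 9))
            splits, dmat, labels = random_additive_tree(n, rng)
            tree, _ = phylo.neighbor_joining(dmat, labels)
            assert phylo.bipartitions(tree) == splits
            paths = phylo.leaf_distances(tree)
            for i in range(n):
                for j in range(i + 1, n):
                    key = tuple(sorted((labels[i], labels[j])))
                    assert paths[key] == pytest.approx(dmat[i, j], abs=1e-9)

    def test_ultrametric_ties_still_additive(self):
        ids = ["A", "B", "C", "D"]
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        tree, _ = phylo.neighbor_joining(d, ids)
        paths = phylo.leaf_distances(tree)
        for i in range(4):
            for j in range(i + 1, 4):
                key = tuple(sorted((ids[i], ids[j])))
                assert paths[key] == pytest.approx(2.0, abs=1e-9)


class TestBootstrap:
    def _two_cluster_alignment(self, L=200, seed=2):
        rng = np.random.default_rng(seed)
        base = "".join(rng.choice(list("ACGT"), L))
        other = list(base)
        for i in range(0, L, 4):  # many columns support the split
            other[i] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[i]]
        other = "".join(other)
        def jitter(s, k, shift):
            out = list(s)
            for i in range(k):
                p = (7 * i + shift) % len(out)
                out[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[out[p]]
            return "".join(out)
        seqs = [base, jitter(base, 2, 1), jitter(base, 2, 3),
                other, jitter(other, 2, 1), jitter(other, 2, 3)]
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        return seqs, ids

    def test_strong_split_gets_high_support(self):
        seqs, ids = self._two_cluster_alignment()
        res = phylo.bootstrap_supports(seqs, ids, n_replicates=200, seed=5)
        splits = {frozenset(n.leaf_names()): n.support
                  for n in res.tree.walk()
                  if not n.is_leaf and n is not res.tree}
        central = [s for split, s in splits.items()
                   if {x[0] for x in split} in ({"a"}, {"b"})
                   and len(split) == 3]
        assert central and all(s >= 95.0 for s in central)

    def test_single_replicate_supports_are_binary(self):
        seqs, ids = self._two_cluster_alignment()
        res = phylo.bootstrap_supports(seqs, ids, n_replicates=1, seed=0)
        sups = [n.support for n in res.tree.walk()
                if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_same_seed_same_supports(self):
        seqs, ids = self._two_cluster_alignment()
        r1 = phylo.bootstrap_supports(seqs, ids, n_replicates=50, seed=9)
        r2 = phylo.bootstrap_supports(seqs, ids, n_replicates=50, seed=9)
        assert phylo.to_newick(r1.tree) == phylo.to_newick(r2.tree)

    def test_supports_invariant_under_taxon_permutation(self):
        seqs, ids = self._two_cluster_alignment()
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ids))
        seqs_p = [seqs[i] for i in perm]
        ids_p = [ids[i] for i in perm]
        r1 = phylo.bootstrap_supports(seqs, ids, n_replicates=100, seed=3)
        r2 = phylo.bootstrap_supports(seqs_p, ids_p, n_replicates=100,
                                      seed=3)
        def support_map(tree):
            out = {}
            for n in tree.walk():
                if not n.is_leaf and n is not tree and n.support is not None:
                    out[frozenset(n.leaf_names())] = n.support
            return out
        assert support_map(r1.tree) == support_map(r2.tree)


class TestRooting:
    def test_outgroup_separated_at_root(self):
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ], dtype=float)
        tree, _ = phylo.neighbor_joining(d, ids)
        rooted = phylo.root_with_outgroup(tree, "D")
        assert len(rooted.children) == 2
        first = rooted.children[0]
        assert first.is_leaf and first.name == "D"
        # path lengths preserved through rerooting
        paths = phylo.leaf_distances(rooted)
        assert paths[("A", "D")] == pytest.approx(6.0, abs=1e-9)

    def test_root_then_unroot_preserves_topology(self):
        ids = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(8)
        from oracles import random_additive_tree
        splits, dmat, labels = random_additive_tree(5, rng)
        tree, _ = phylo.neighbor_joining(dmat, labels)
        rooted = phylo.root_with_outgroup(tree, labels[0])
        unrooted = phylo.unroot(rooted)
        assert phylo.bipartitions(unrooted) == phylo.bipartitions(tree)

    def test_missing_outgroup_rejected(self):
        tree, _ = phylo.neighbor_joining(
            np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float),
            ["A", "B", "C"])
        with pytest.raises(ValueError, match="nope"):
            phylo.root_with_outgroup(tree, "nope")


class TestNewick:
    def test_write_read_write_identical_text(self, tmp_path):
        ids = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            dtype=float)
        tree, _ = phylo.neighbor_joining(d, ids)
        text1 = phylo.to_newick(tree)
        path = tmp_path / "t.nwk"
        phylo.write_newick(tree, path)
        back = phylo.read_newick(path)
        assert phylo.to_newick(back) == text1

    def test_supports_serialized_as_internal_labels(self):
        inner = phylo.TreeNode(support=87.0, length=1.0, children=[
            phylo.TreeNode(name="A", length=1.0),
            phylo.TreeNode(name="B", length=2.0)])
        tree = phylo.TreeNode(children=[
            inner, phylo.TreeNode(name="C", length=0.5)])
        assert phylo.to_newick(tree) == "((A:1,B:2)87:1,C:0.5);"

    def test_round_trip_lengths_and_supports(self):
        text = "((A:1.25,B:2.5)93:0.75,C:0.5,D:4);"
        tree = phylo.parse_newick(text)
        assert phylo.to_newick(tree) == text

    def test_unbalanced_parenthesis_rejected(self):
        with pytest.raises(phylo.NewickParseError):
            phylo.parse_newick("((A:1,B:2;")

    def test_independent_parser_agrees_on_path_lengths(self):
        # cross-check the serializer against dendropy's parser
        import dendropy

        rng = np.random.default_rng(12)
        _, dmat, labels = random_additive_tree(6, rng)
        tree, _ = phylo.neighbor_joining(dmat, labels)
        dtree = dendropy.Tree.get(data=phylo.to_newick(tree),
                                  schema="newick")
        pdm = dtree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dtree.taxon_namespace}
        ours = phylo.leaf_distances(tree)
        for (a, b), d in ours.items():
            assert pdm.patristic_distance(taxa[a], taxa[b]) == \
                pytest.approx(d, abs=1e-9)
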