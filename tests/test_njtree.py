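"""Neighbour joining, bootstrap support and species-cohesion tests."""

import numpy as np
import pytest

import barcode_audit as ba
from conftest import toy_matrix, toy_taxonomy


def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree as an edge-weighted networkx graph.

    Independent oracle: leaves are attached one at a time by splitting a
    random existing edge; path lengths on the resulting graph form an
    additive matrix whose unique generating tree is the graph itself.
    """
    import networkx as nx

    g = nx.Graph()
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    g.add_edge(labels[0], "i0", weight=rng.uniform(0.05, 0.5))
    g.add_edge(labels[1], "i0", weight=rng.uniform(0.05, 0.5))
    g.add_edge(labels[2], "i0", weight=rng.uniform(0.05, 0.5))
    next_internal = 1
    for leaf in labels[3:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["weight"]
        g.remove_edge(u, v)
        mid = f"i{next_internal}"
        next_internal += 1
        frac = rng.uniform(0.2, 0.8)
        g.add_edge(u, mid, weight=w * frac)
        g.add_edge(mid, v, weight=w * (1 - frac))
        g.add_edge(mid, leaf, weight=rng.uniform(0.05, 0.5))
    return g, labels


def additive_matrix(g, labels):
    import networkx as nx

    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    n = len(labels)
    values = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            values[a, b] = values[b, a] = paths[labels[a]][labels[b]]
    return ba.DistanceMatrix(list(labels), values)


def graph_bipartitions(g, labels):
    import networkx as nx

    ref = min(labels)
    labelset = set(labels)
    splits = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        side = {n for n in nx.node_connected_component(h, u) if n in labelset}
        if ref in side:
            side = labelset - side
        if 2 <= len(side) <= len(labelset) - 2:
            splits.add(frozenset(side))
    return splits


class TestNJ:
    def test_two_taxa_split_distance(self):
        dm = toy_matrix(["A", "B"], {("A", "B"): 0.1})
        tree = ba.nj(dm)
        d = tree.leaf_distances()
        assert d.get("A", "B") == pytest.approx(0.1)
        nwk = tree.newick()
        assert "0.05" in nwk  # each pendant edge d/2

    def test_three_taxa_closed_form(self):
        dm = toy_matrix(
            ["A", "B", "C"],
            {("A", "B"): 0.3, ("A", "C"): 0.5, ("B", "C"): 0.6},
        )
        tree = ba.nj(dm)
        # x_A = (d_AB + d_AC - d_BC)/2 etc.
        d = tree.leaf_distances()
        assert d.get("A", "B") == pytest.approx(0.3, abs=1e-12)
        assert d.get("A", "C") == pytest.approx(0.5, abs=1e-12)
        assert d.get("B", "C") == pytest.approx(0.6, abs=1e-12)

    @pytest.mark.parametrize("n_leaves", [6, 8, 10])
    def test_recovers_additive_tree(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            g, labels = random_additive_tree(rng, n_leaves)
            dm = additive_matrix(g, labels)
            tree = ba.nj(dm)
            assert set(tree.bipartitions()) == graph_bipartitions(g, labels)
            rec = tree.leaf_distances()
            for a in range(n_leaves):
                for b in range(a + 1, n_leaves):
                    assert rec.values[a, b] == pytest.approx(
                        dm.values[a, b], abs=1e-9
                    )

    def test_agrees_with_independent_nj_implementation(self):
        # non-additive (noisy) matrix: same unrooted topology as scikit-bio
        import skbio

        rng = np.random.default_rng(42)
        g, labels = random_additive_tree(rng, 8)
        dm = additive_matrix(g, labels)
        noisy = dm.values + rng.uniform(0, 0.01, dm.values.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = ba.nj(ba.DistanceMatrix(list(labels), noisy))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=labels))
        ref = min(labels)
        labelset = set(labels)
        sk_splits = set()
        for node in sk_tree.non_tips(include_self=False):
            side = {t.name for t in node.tips()}
            if ref in side:
                side = labelset - side
            if 2 <= len(side) <= len(labelset) - 2:
                sk_splits.add(frozenset(side))
        assert set(ours.bipartitions()) == sk_splits

    def test_label_order_invariance(self):
        rng = np.random.default_rng(5)
        g, labels = random_additive_tree(rng, 7)
        dm = additive_matrix(g, labels)
        perm = list(reversed(labels))
        idx = [labels.index(l) for l in perm]
        dm_perm = ba.DistanceMatrix(perm, dm.values[np.ix_(idx, idx)])
        assert set(ba.nj(dm).bipartitions()) == set(ba.nj(dm_perm).bipartitions())

    def test_undefined_pairs_rejected(self):
        values = np.array([[0.0, np.nan, 0.1], [np.nan, 0.0, 0.1], [0.1, 0.1, 0.0]])
        dm = ba.DistanceMatrix(["a", "b", "c"], values, {frozenset(("a", "b"))})
        with pytest.raises(ValueError, match="drop"):
            ba.nj(dm)

    def test_branch_lengths_never_negative(self, sim_dm):
        sub = sim_dm.submatrix(sim_dm.labels[:40])
        tree = ba.nj(sub)
        for edge in tree._dtree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0


class TestExclusiveCluster:
    def _tax(self):
        return toy_taxonomy({
            "A1": ("A", "G", "F", "O"), "A2": ("A", "G", "F", "O"),
            "B1": ("B", "G", "F", "O"), "B2": ("B", "G", "F", "O"),
        })

    def test_cohesive_species_exclusive(self):
        tree = ba.Tree.from_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        tax = self._tax()
        assert ba.is_exclusive_cluster(tree, "A", tax)
        assert ba.is_exclusive_cluster(tree, "B", tax)

    def test_interleaved_species_not_exclusive(self):
        tree = ba.Tree.from_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        tax = self._tax()
        assert not ba.is_exclusive_cluster(tree, "A", tax)
        assert not ba.is_exclusive_cluster(tree, "B", tax)

    def test_single_specimen_trivially_exclusive(self):
        tree = ba.Tree.from_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);")
        tax = toy_taxonomy({
            "A1": ("A", "G", "F", "O"), "B1": ("B", "G", "F", "O"),
            "A2": ("C", "G", "F", "O"), "B2": ("D", "G", "F", "O"),
        })
        assert ba.is_exclusive_cluster(tree, "A", tax)

    def test_absent_species_errors(self):
        tree = ba.Tree.from_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);")
        with pytest.raises(ValueError, match="absent"):
            ba.is_exclusive_cluster(tree, "Z", self._tax())


class TestBootstrap:
    def test_uniform_signal_gives_full_support(self):
        # ten columns all support the same split; no conflicting signal
        a = "A" * 60
        b = "A" * 59 + "C"
        c = "G" * 10 + "A" * 50
        d = "G" * 10 + "A" * 49 + "C"
        recs = [("a", a), ("b", b), ("c", c), ("d", d)]
        tree = ba.bootstrap_support(recs, n_reps=50, seed=1)
        supports = tree.supports()
        assert supports, "expected at least one internal split"
        # the ab|cd split is present in every pseudoreplicate; its
        # normalised key is the side not containing the smallest label
        assert supports[frozenset(("c", "d"))] == pytest.approx(100.0)

    def test_supports_bounded_and_reproducible(self, sim_dataset):
        recs = sim_dataset.records[:12]
        t1 = ba.bootstrap_support(recs, n_reps=30, seed=9)
        t2 = ba.bootstrap_support(recs, n_reps=30, seed=9)
        s1, s2 = t1.supports(), t2.supports()
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())

    def test_strong_split_outranks_weak_split(self):
        rng = np.random.default_rng(0)
        L = 200
        base = rng.integers(0, 4, size=L)
        nuc = "ACGT"

        def seq(arr):
            return "".join(nuc[x] for x in arr)

        group_b = base.copy()
        group_b[:40] = (group_b[:40] + 2) % 4      # strong split: 40 sites
        # weak split {a2, a3}: 2 shared sites; 1 conflicting site pulls
        # a1 and a2 together whenever the weak columns go unsampled
        a1, a2, a3 = base.copy(), base.copy(), base.copy()
        a1[55] = (a1[55] + 2) % 4
        a2[50:52] = (a2[50:52] + 2) % 4
        a2[55] = (a2[55] + 2) % 4
        a3[50:52] = (a3[50:52] + 2) % 4
        b1, b2, b3 = group_b.copy(), group_b.copy(), group_b.copy()
        b1[60] = (b1[60] + 2) % 4
        recs = [("a1", seq(a1)), ("a2", seq(a2)), ("a3", seq(a3)),
                ("b1", seq(b1)), ("b2", seq(b2)), ("b3", seq(b3))]
        tree = ba.bootstrap_support(recs, n_reps=300, seed=4)
        supports = tree.supports()
        strong = frozenset(("b1", "b2", "b3"))
        weak = frozenset(("a2", "a3"))
        assert strong in supports and weak in supports
        assert supports[strong] > supports[weak]
        assert supports[strong] > 95.0
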