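"""Neighbor joining, bootstrap supports, clade assignment."""
import dendropy
import numpy as np
import pytest

from comcensus.genome_io import Msa
from comcensus.phylo import (assign_clades, bootstrap_support, distance_matrix,
                             neighbor_joining, split_support)


def random_additive_tree(n_taxa, rng):
    """Random binary topology with positive branch lengths; returns
    (dendropy tree, names, path-distance matrix) - the additivity oracle.

    The matrix is computed by explicit leaf-to-leaf path summation,
    independently of any reconstruction code."""
    names = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(names)
    nodes = [dendropy.Node(taxon=tns.get_taxon(nm)) for nm in names]
    # leaf set below each node, for path distances
    below = [{i} for i in range(n_taxa)]
    active = list(range(n_taxa))
    dists = np.zeros((n_taxa, n_taxa))
    depth = [0.0] * n_taxa  # distance from node to its own leaves (max-free: use per-leaf)
    dist_to_node = [dict({i: 0.0}) for i in range(n_taxa)]
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        la, lb = float(rng.uniform(0.05, 1.0)), float(rng.uniform(0.05, 1.0))
        parent = dendropy.Node()
        parent.add_child(nodes[a]); nodes[a].edge.length = la
        parent.add_child(nodes[b]); nodes[b].edge.length = lb
        nodes.append(parent)
        d_new = {}
        for leaf, d in dist_to_node[a].items():
            d_new[leaf] = d + la
        for leaf, d in dist_to_node[b].items():
            d_new[leaf] = d + lb
        for x in dist_to_node[a]:
            for y in dist_to_node[b]:
                dists[x, y] = dists[y, x] = dist_to_node[a][x] + la + dist_to_node[b][y] + lb
        dist_to_node.append(d_new)
        active = [n for k, n in enumerate(active) if k not in (i, j)] + [len(nodes) - 1]
    a, b = active
    lab = float(rng.uniform(0.05, 1.0))
    root = dendropy.Node()
    root.add_child(nodes[a]); nodes[a].edge.length = lab / 2
    root.add_child(nodes[b]); nodes[b].edge.length = lab / 2
    for x in dist_to_node[a]:
        for y in dist_to_node[b]:
            dists[x, y] = dists[y, x] = dist_to_node[a][x] + dist_to_node[b][y] + lab
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree, names, dists


def rf_distance(t1, t2):
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestDistanceMatrix:
    def test_identical_sequences_give_zero_matrix(self):
        msa = Msa(names=["a", "b", "c"], rows=["ACDE"] * 3)
        _, D = distance_matrix(msa)
        assert np.all(D == 0)

    def test_symmetry_and_hand_values(self):
        msa = Msa(names=["a", "b", "c", "d"],
                  rows=["ACDEFGHI", "ACDEFGHW", "ACDEYYHI", "WWDEFGHI"])
        names, D = distance_matrix(msa)
        assert np.allclose(D, D.T)
        assert D[0, 1] == pytest.approx(1 / 8)
        assert D[0, 2] == pytest.approx(2 / 8)
        assert D[1, 3] == pytest.approx(3 / 8)

    def test_incomparable_pair_names_sequences(self):
        msa = Msa(names=["a", "b", "c"], rows=["A---", "-C--", "AC--"])
        with pytest.raises(ValueError, match="'a'.*'b'"):
            distance_matrix(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        lt = neighbor_joining(D, ["a", "b", "c"])
        lengths = {l.taxon.label: l.edge.length for l in lt.tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_recovers_additive_four_taxon_tree(self):
        rng = np.random.default_rng(3)
        tree, names, D = random_additive_tree(4, rng)
        lt = neighbor_joining(D, names, taxon_namespace=tree.taxon_namespace)
        lt.tree.encode_bipartitions()
        tree.encode_bipartitions()
        assert rf_distance(tree, lt.tree) == 0
        # branch lengths: leaf edges must match the generating tree
        gen = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        got = {l.taxon.label: l.edge.length for l in lt.tree.leaf_node_iter()}
        for k in gen:
            assert got[k] == pytest.approx(gen[k], abs=1e-9)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            n = int(rng.integers(4, 13))
            tree, names, D = random_additive_tree(n, rng)
            lt = neighbor_joining(D, names, taxon_namespace=tree.taxon_namespace)
            lt.tree.encode_bipartitions()
            tree.encode_bipartitions()
            assert rf_distance(tree, lt.tree) == 0

    def test_two_clade_ultrametric_bipartition(self):
        # block matrix: within 0.2, between 1.0
        n = 6
        D = np.full((n, n), 1.0)
        D[:3, :3] = 0.2
        D[3:, 3:] = 0.2
        np.fill_diagonal(D, 0.0)
        names = [f"t{i}" for i in range(n)]
        lt = neighbor_joining(D, names)
        masks = set()
        lt.tree.encode_bipartitions()
        tns = lt.tree.taxon_namespace
        want = sum(int(tns.taxon_bitmask(t)) for t in tns if t.label in {"t0", "t1", "t2"})
        full = (1 << n) - 1
        for edge in lt.tree.preorder_edge_iter():
            if edge.bipartition is not None:
                m = int(edge.bipartition.split_bitmask)
                masks.update({m, full ^ m})
        assert want in masks

    def test_asymmetric_matrix_is_error(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(D, list("abc"))

    def test_upgma_recovers_ultrametric_clades(self):
        from comcensus.phylo import upgma
        n = 6
        D = np.full((n, n), 1.0)
        D[:3, :3] = 0.2
        D[3:, 3:] = 0.2
        np.fill_diagonal(D, 0.0)
        names = [f"t{i}" for i in range(n)]
        lt = upgma(D, names)
        lt.tree.encode_bipartitions()
        tns = lt.tree.taxon_namespace
        want = sum(int(tns.taxon_bitmask(t)) for t in tns
                   if t.label in {"t0", "t1", "t2"})
        full = (1 << n) - 1
        masks = set()
        for edge in lt.tree.preorder_edge_iter():
            if edge.bipartition is not None:
                m = int(edge.bipartition.split_bitmask)
                masks.update({m, full ^ m})
        assert want in masks
        # ultrametric: every leaf sits at the same root depth
        root_dists = [l.distance_from_root() for l in lt.tree.leaf_node_iter()]
        assert max(root_dists) - min(root_dists) < 1e-9


@pytest.fixture(scope="module")
def two_clade_msa():
    from comcensus.synth import ancestors, evolve_family
    seqs, clade_of = evolve_family(ancestors()["ComQ"], {"c1": 6, "c2": 6},
                                   0.15, 0.6, seed=11)
    names = list(seqs)
    return Msa(names=names, rows=[seqs[n] for n in names]), clade_of


class TestBootstrap:

    def test_single_replicate_supports_are_zero_or_hundred(self, two_clade_msa):
        msa, _ = two_clade_msa
        lt = bootstrap_support(msa, n_reps=1, seed=5)
        assert set(lt.supports.values()) <= {0.0, 100.0}

    def test_seed_determinism(self, two_clade_msa):
        msa, _ = two_clade_msa
        a = bootstrap_support(msa, n_reps=20, seed=9)
        b = bootstrap_support(msa, n_reps=20, seed=9)
        assert a.supports == b.supports

    def test_clear_clades_get_high_root_support(self, two_clade_msa):
        msa, clade_of = two_clade_msa
        lt = bootstrap_support(msa, n_reps=100, seed=13)
        clade1 = {n for n in msa.names if clade_of[n] == "c1"}
        s = split_support(lt, clade1)
        assert s is not None and s >= 95

    def test_supports_invariant_to_leaf_order(self, two_clade_msa):
        msa, _ = two_clade_msa
        perm = list(reversed(range(msa.n_rows)))
        msa2 = Msa(names=[msa.names[i] for i in perm],
                   rows=[msa.rows[i] for i in perm])
        a = bootstrap_support(msa, n_reps=50, seed=21)
        b = bootstrap_support(msa2, n_reps=50, seed=21)
        clade = set(msa.names[:6])
        assert split_support(a, clade) == split_support(b, clade)


class TestAssignClades:
    def test_synth_tree_assignment_matches_ground_truth(self):
        """Anchors spanning each clade recover the ground-truth labels."""
        from comcensus.synth import ancestors, evolve_family
        seqs, clade_of = evolve_family(ancestors()["ComQ"], {"c1": 8, "c2": 8},
                                       0.12, 0.6, seed=23)
        names = list(seqs)
        msa = Msa(names=names, rows=[seqs[n] for n in names])
        nm, D = distance_matrix(msa)
        lt = neighbor_joining(D, nm)
        anchors = dict(clade_of)  # full anchor sets span the clades exactly
        lt = assign_clades(lt, anchors)
        for n in names:
            assert lt.clade[n] == clade_of[n]

    def test_sparse_anchors_give_contained_monophyletic_groups(self):
        """With few anchors the smallest containing clan may be a proper
        subset of the true clade but never crosses into the other clade."""
        from comcensus.synth import ancestors, evolve_family
        seqs, clade_of = evolve_family(ancestors()["ComQ"], {"c1": 8, "c2": 8},
                                       0.12, 0.6, seed=23)
        names = list(seqs)
        msa = Msa(names=names, rows=[seqs[n] for n in names])
        nm, D = distance_matrix(msa)
        lt = neighbor_joining(D, nm)
        anchors = {"c1_000": "c1", "c1_001": "c1", "c2_000": "c2", "c2_001": "c2"}
        lt = assign_clades(lt, anchors)
        for n in names:
            if lt.clade[n] != "unassigned":
                assert lt.clade[n] == clade_of[n]
        for a, c in anchors.items():
            assert lt.clade[a] == c

    def test_four_leaf_single_anchor_assignment(self):
        D = np.array([[0, .1, .9, .9], [.1, 0, .9, .9],
                      [.9, .9, 0, .1], [.9, .9, .1, 0.0]])
        lt = neighbor_joining(D, list("abcd"))
        lt = assign_clades(lt, {"a": "left", "c": "right"})
        assert lt.clade["a"] == "left" and lt.clade["b"] in {"left", "unassigned"}
        assert lt.clade["c"] == "right"

    def test_missing_anchor_is_error(self):
        D = np.array([[0, .1, .9], [.1, 0, .9], [.9, .9, 0.0]])
        lt = neighbor_joining(D, list("abc"))
        with pytest.raises(ValueError, match="not in tree"):
            assign_clades(lt, {"a": "x", "zzz": "y"})

    def test_interleaved_anchors_are_error(self):
        from comcensus.synth import ancestors, evolve_family
        seqs, clade_of = evolve_family(ancestors()["ComQ"], {"c1": 4, "c2": 4},
                                       0.1, 0.8, seed=31)
        names = list(seqs)
        msa = Msa(names=names, rows=[seqs[n] for n in names])
        nm, D = distance_matrix(msa)
        lt = neighbor_joining(D, nm)
        # anchors deliberately mix the clades -> cannot be monophyletic
        anchors = {"c1_000": "x", "c2_000": "x", "c1_001": "y", "c2_001": "y"}
        with pytest.raises(ValueError, match="monophyletic"):
            assign_clades(lt, anchors)
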