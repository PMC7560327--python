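"""Distances, neighbor joining, consensus, duplication calls, asymmetry."""

import math

import dendropy
import numpy as np
import pytest

from dupscape import genetree
from dupscape.genetree import DistanceMatrix, GeneTreeError
from dupscape.species_tree import SpeciesPhylogeny
from oracles import duplication_nodes_brute, random_binary_tree


def _random_additive(rng, n_taxa):
    """A random dated tree and its exact additive distance matrix."""
    labels = [f"S{i}|g" for i in range(n_taxa)]
    tree = random_binary_tree(labels, rng)
    taxa = tree.taxon_namespace
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_taxa, n_taxa))
    for i, t1 in enumerate(taxa):
        for j, t2 in enumerate(taxa):
            if i != j:
                d[i, j] = pdm.patristic_distance(t1, t2)
    return tree, DistanceMatrix(tuple(labels), d)


def _patristic(tree):
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    ns = tree.taxon_namespace
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[(a, b)] = pdm.patristic_distance(
                ns.get_taxon(a), ns.get_taxon(b)
            )
    return out


class TestProteinDistance:
    def test_identical_sequences_give_zero(self):
        aln = {"a|x": "MKTAY", "b|x": "MKTAY", "c|x": "MKTAY"}
        dm = genetree.protein_distance(aln)
        assert np.allclose(dm.values, 0)

    def test_formula_at_ten_percent_difference(self):
        a = "A" * 9 + "C"
        aln = {"a|x": a, "b|x": "A" * 10, "c|x": a}
        dm = genetree.protein_distance(aln)
        expected = -math.log(1 - 0.1 - 0.2 * 0.01)
        i, j = dm.labels.index("a|x"), dm.labels.index("b|x")
        assert dm.values[i, j] == pytest.approx(expected)

    def test_cap_and_flag_at_high_divergence(self):
        aln = {"a|x": "A" * 20, "b|x": "C" * 20, "c|x": "A" * 20}
        dm = genetree.protein_distance(aln)
        assert dm.capped
        assert np.isfinite(dm.values).all()

    def test_symmetric_under_reordering(self):
        aln = {"a|x": "MKTAYIAK", "b|x": "MKTWYIAK", "c|x": "MKAAYIAK"}
        d1 = genetree.protein_distance(aln)
        d2 = genetree.protein_distance(dict(reversed(list(aln.items()))))
        for x in aln:
            for y in aln:
                i1, j1 = d1.labels.index(x), d1.labels.index(y)
                i2, j2 = d2.labels.index(x), d2.labels.index(y)
                assert d1.values[i1, j1] == pytest.approx(d2.values[i2, j2])

    def test_no_shared_columns_rejected(self):
        aln = {"a|x": "M---", "b|x": "-K--", "c|x": "--W-"}
        with pytest.raises(GeneTreeError):
            genetree.protein_distance(aln)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = genetree.nj_build(DistanceMatrix(("a", "b", "c"), d))
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    def test_exact_recovery_on_additive_matrices(self, rng):
        for _ in range(25):
            true_tree, dm = _random_additive(rng, 5)
            recovered = genetree.nj_build(dm)
            want = _patristic(true_tree)
            got = _patristic(recovered)
            for pair, dist in want.items():
                assert got[pair] == pytest.approx(dist, abs=1e-9)

    def test_topology_matches_independent_nj_oracle(self, rng):
        # random (noisy, non-additive) matrices against dendropy's NJ
        for _ in range(15):
            n = 6
            noise = rng.uniform(0.1, 1.0, size=(n, n))
            d = (noise + noise.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = tuple(f"t{i}|g" for i in range(n))
            mine = genetree.nj_build(DistanceMatrix(labels, d))
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                src=_as_csv(labels, d), delimiter=","
            )
            oracle = pdm.nj_tree()
            assert _bipartition_set(mine) == _bipartition_set(oracle)

    def test_fewer_than_three_taxa_rejected(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(GeneTreeError):
            genetree.nj_build(DistanceMatrix(("a", "b"), d))

    def test_no_negative_branch_lengths(self, rng):
        for _ in range(10):
            n = 6
            noise = rng.uniform(0.01, 1.0, size=(n, n))
            d = (noise + noise.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = genetree.nj_build(DistanceMatrix(tuple(f"t{i}" for i in range(n)), d))
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0


def _as_csv(labels, d):
    import io

    out = io.StringIO()
    out.write("," + ",".join(labels) + "\n")
    for lab, row in zip(labels, d):
        out.write(lab + "," + ",".join(map(str, row)) + "\n")
    out.seek(0)
    return out


def _bipartition_set(tree):
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(leaves)
    bips = set()
    for node in tree.preorder_internal_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = clade if ref not in clade else leaves - clade
        if 2 <= len(side) <= len(leaves) - 2:
            bips.add(side)
    return bips


class TestBootstrapConsensus:
    def _structured_alignment(self):
        # two well-separated clades with many diagnostic columns
        return {
            "A|1": "MMMMMMKKKKKK" * 4,
            "A|2": "MMMMMMKKKKKR" * 4,
            "B|1": "WWWWWWEEEEEE" * 4,
            "B|2": "WWWWWWEEEEER" * 4,
            "C|1": "MMMWWWKKKEEE" * 4,
        }

    def test_true_clades_get_high_support(self):
        tree = genetree.bootstrap_consensus(self._structured_alignment(), replicates=50, seed=3)
        supports = {
            frozenset(lf.taxon.label for lf in node.leaf_iter()): node.support
            for node in tree.preorder_internal_node_iter()
            if node is not tree.seed_node
        }
        assert supports[frozenset({"B|1", "B|2"})] >= 95

    def test_seeded_runs_reproducible(self):
        aln = self._structured_alignment()
        t1 = genetree.bootstrap_consensus(aln, replicates=30, seed=9)
        t2 = genetree.bootstrap_consensus(aln, replicates=30, seed=9)
        assert t1.as_string(schema="newick") == t2.as_string(schema="newick")

    def test_supports_within_bounds_and_majority(self):
        tree = genetree.bootstrap_consensus(self._structured_alignment(), replicates=40, seed=1)
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node or node.support is None:
                continue
            assert 50 < node.support <= 100

    def test_zero_replicates_rejected(self):
        with pytest.raises(GeneTreeError):
            genetree.bootstrap_consensus(self._structured_alignment(), replicates=0)


def _tree(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestDetectDuplications:
    def test_terminal_duplication(self):
        calls = genetree.detect_duplications(
            _tree("((Dmel|a:1,Dmel|b:1):1,Agam|a:2);"), rooted=True
        )
        assert len(calls) == 1
        assert calls[0].species_a == calls[0].species_b == frozenset({"Dmel"})

    def test_shared_duplication_at_ancestor(self):
        calls = genetree.detect_duplications(
            _tree("(((Dmel|a:1,Agam|a:1):1,(Dmel|b:1,Agam|b:1):1):1,Tcas|a:2);"),
            rooted=True,
        )
        assert len(calls) == 1
        assert calls[0].species_a & calls[0].species_b == {"Dmel", "Agam"}

    def test_ladder_without_repeats_has_no_calls(self):
        calls = genetree.detect_duplications(
            _tree("(Amel|a:1,(Tcas|a:1,(Agam|a:1,Dmel|a:1):1):1);"), rooted=True
        )
        assert calls == []

    def test_matches_brute_force_on_random_trees(self, rng):
        species = ["Dmel", "Agam", "Tcas", "Amel"]
        for _ in range(30):
            n = int(rng.integers(4, 11))
            labels = [f"{species[int(rng.integers(4))]}|g{i}" for i in range(n)]
            tree = random_binary_tree(labels, rng)
            expected = duplication_nodes_brute(tree)
            calls = genetree.detect_duplications(tree, rooted=True)
            got = {
                frozenset(call.leaves_a) | frozenset(call.leaves_b) for call in calls
            }
            got_full = set()
            for call in calls:
                # reconstruct the node's full leaf set for comparison
                node = None
                for idx, nd in enumerate(tree.preorder_node_iter()):
                    if idx == call.node_id:
                        node = nd
                got_full.add(frozenset(lf.taxon.label for lf in node.leaf_iter()))
            assert got_full == expected

    def test_unlabeled_leaf_rejected(self):
        tree = _tree("((a:1,b:1):1,c:2);")
        with pytest.raises(GeneTreeError):
            genetree.detect_duplications(tree, rooted=True)


class TestBranchMapping:
    def test_single_species_maps_to_terminal(self, insect_tree):
        calls = genetree.detect_duplications(
            _tree("((Dmel|a:1,Dmel|b:1):1,Agam|a:2);"), rooted=True
        )
        assert genetree.map_to_species_branch(calls[0], insect_tree) == "Dmel"

    def test_two_species_map_to_their_stem(self, insect_tree):
        calls = genetree.detect_duplications(
            _tree("(((Dmel|a:1,Agam|a:1):1,(Dmel|b:1,Agam|b:1):1):1,Tcas|a:2);"),
            rooted=True,
        )
        assert genetree.map_to_species_branch(calls[0], insect_tree) == "Agam+Dmel"

    def test_deeper_union_maps_above_lca(self):
        sp = SpeciesPhylogeny.from_newick(
            "(Mdes:280,((Dwil:60,Dmel:60):190,Ccap:250):30);"
        )
        calls = genetree.detect_duplications(
            _tree("(((Dmel|a:1,Dwil|a:1):1,(Dmel|b:1,Dwil|b:1):1):1,Ccap|a:2);"),
            rooted=True,
        )
        assert genetree.map_to_species_branch(calls[0], sp) == "Dmel+Dwil"

    def test_unknown_species_rejected(self, insect_tree):
        calls = genetree.detect_duplications(
            _tree("((Xeno|a:1,Xeno|b:1):1,Dmel|a:2);"), rooted=True
        )
        with pytest.raises(Exception):
            genetree.map_to_species_branch(calls[0], insect_tree)


class TestOutgroupTiming:
    @pytest.mark.parametrize(
        "count, verdict",
        [(2, "pre_split"), (5, "pre_split"), (1, "post_split"), (0, "indeterminate")],
    )
    def test_verdicts(self, count, verdict):
        assert genetree.timing_by_outgroup(count) == verdict

    def test_negative_count_rejected(self):
        with pytest.raises(GeneTreeError):
            genetree.timing_by_outgroup(-1)


class TestAsymmetry:
    def test_threefold_pair_is_asymmetric(self):
        tree = _tree("((Dmel|a:0.30,Dmel|b:0.10):0.2,(Agam|a:0.2,Tcas|a:0.2):0.2);")
        calls = genetree.asymmetry(tree, pairs=[("Dmel|a", "Dmel|b")])
        assert calls[0].ratio == pytest.approx(3.0)
        assert calls[0].asymmetric

    def test_equal_lengths_not_asymmetric(self):
        tree = _tree("((Dmel|a:0.2,Dmel|b:0.2):0.2,(Agam|a:0.2,Tcas|a:0.2):0.2);")
        calls = genetree.asymmetry(tree, pairs=[("Dmel|a", "Dmel|b")])
        assert calls[0].ratio == pytest.approx(1.0)
        assert not calls[0].asymmetric

    def test_strict_boundary_at_two(self):
        tree21 = _tree("((Dmel|a:0.21,Dmel|b:0.10):0.2,(Agam|a:0.2,Tcas|a:0.2):0.1);")
        tree20 = _tree("((Dmel|a:0.20,Dmel|b:0.10):0.2,(Agam|a:0.2,Tcas|a:0.2):0.1);")
        assert genetree.asymmetry(tree21, pairs=[("Dmel|a", "Dmel|b")])[0].asymmetric
        assert not genetree.asymmetry(tree20, pairs=[("Dmel|a", "Dmel|b")])[0].asymmetric

    def test_zero_length_flagged_infinite_with_warning(self):
        tree = _tree("((Dmel|a:0.3,Dmel|b:0.0):0.2,(Agam|a:0.2,Tcas|a:0.2):0.1);")
        with pytest.warns(UserWarning, match="zero-length"):
            calls = genetree.asymmetry(tree, pairs=[("Dmel|a", "Dmel|b")])
        assert math.isinf(calls[0].ratio)
        assert calls[0].asymmetric
        assert calls[0].note

    def test_clade_level_paths_sum_from_duplication_node(self):
        # duplication node joins a two-leaf clade and one leaf: the clade
        # side's length is the mean root-to-tip path below it
        tree = _tree(
            "(((Dmel|a:0.1,Dmel|b:0.3):0.2,Dmel|c:0.1):0.5,(Agam|a:0.2,Tcas|a:0.2):0.5);"
        )
        calls = genetree.asymmetry(tree, rooted=True)
        by_sides = {tuple(sorted(c.side_a + c.side_b)): c for c in calls}
        call = by_sides[("Dmel|a", "Dmel|b", "Dmel|c")]
        assert call.length_a == pytest.approx(0.4)  # mean(0.3, 0.5)
        assert call.length_b == pytest.approx(0.1)
        assert call.asymmetric

    def test_missing_pair_rejected(self):
        tree = _tree("((Dmel|a:0.3,Dmel|b:0.1):0.2,(Agam|a:0.2,Tcas|a:0.2):0.1);")
        with pytest.raises(GeneTreeError):
            genetree.asymmetry(tree, pairs=[("Dmel|a", "Dmel|zzz")])


class TestRooting:
    def test_midpoint_preserves_leaf_set_on_extreme_branch(self):
        # an extremely long terminal branch puts the midpoint on that leaf
        dm = DistanceMatrix(
            ("Dmel|a", "Dmel|b", "Agam|a", "Tcas|a"),
            np.array(
                [
                    [0.0, 5.0, 0.4, 0.5],
                    [5.0, 0.0, 5.2, 5.3],
                    [0.4, 5.2, 0.0, 0.3],
                    [0.5, 5.3, 0.3, 0.0],
                ]
            ),
        )
        tree = genetree.nj_build(dm)
        rooted = genetree.root_tree(tree)
        assert sorted(genetree.leaf_labels(rooted)) == [
            "Agam|a",
            "Dmel|a",
            "Dmel|b",
            "Tcas|a",
        ]

    def test_outgroup_rooting_places_outgroup_basal(self):
        tree = genetree.nj_build(
            DistanceMatrix(
                ("Dmel|a", "Dmel|b", "Amel|a"),
                np.array([[0.0, 0.2, 1.0], [0.2, 0.0, 1.0], [1.0, 1.0, 0.0]]),
            )
        )
        rooted = genetree.root_tree(tree, outgroup_species="Amel")
        children = rooted.seed_node.child_nodes()
        leafsets = [
            frozenset(lf.taxon.label for lf in ch.leaf_iter()) for ch in children
        ]
        assert frozenset({"Amel|a"}) in leafsets
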