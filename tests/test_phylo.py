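"""Branch features, Faith's PD, vulnerability and PD classes."""

import dendropy
import numpy as np
import pytest

from conftest import random_presences
from oracles import descendant_tips, pd_induced_subtree, quantile_classes_by_rank
from phyloprior.grid import PresenceMatrix
from phyloprior.phylo import (
    branch_occurrences,
    compute_csh,
    faith_pd_per_cell,
    graft_and_resolve,
    pd_quantile_classes,
)
from phyloprior.sdm import BinaryRange
from phyloprior.synthetic import simulate_tree


def tree_abc():
    """((A:1,B:1):1,C:2); total length 5."""
    return dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick")


class TestGraft:
    @pytest.fixture()
    def backbone(self):
        t = simulate_tree(5, seed=3)
        for i, lf in enumerate(t.leaf_node_iter()):
            lf.taxon.label = f"g{i}"
        return t

    def test_singleton_genus_renamed_no_new_nodes(self, backbone):
        membership = {f"s{i}": f"g{i}" for i in range(5)}
        out = graft_and_resolve(backbone, membership, seed=0)
        assert sorted(lf.taxon.label for lf in out.leaf_node_iter()) == \
            sorted(membership)
        n_internal = sum(1 for n in out.preorder_node_iter() if not n.is_leaf())
        assert n_internal == 4  # unchanged backbone topology

    def test_k_species_add_k_minus_one_nodes(self, backbone):
        membership = {f"s{i}": "g0" for i in range(6)} | {"t1": "g1"}
        out = graft_and_resolve(backbone, membership, seed=1)
        assert len(out.leaf_nodes()) == 7
        n_internal = sum(1 for n in out.preorder_node_iter() if not n.is_leaf())
        # pruning the 3 empty genera leaves 1 backbone internal node on the
        # path, plus 5 new nodes inside g0
        assert n_internal == 1 + (6 - 1)

    def test_ultrametricity_preserved(self, backbone):
        membership = {f"s{i}": f"g{i % 5}" for i in range(23)}
        out = graft_and_resolve(backbone, membership, seed=2)
        depths = [lf.distance_from_root() for lf in out.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        assert min(e.length for e in out.preorder_edge_iter()
                   if e.length is not None) > 0

    def test_same_seed_identical_newick(self, backbone):
        membership = {f"s{i}": f"g{i % 3}" for i in range(12)}
        a = graft_and_resolve(backbone, membership, seed=7)
        b = graft_and_resolve(backbone, membership, seed=7)
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_unknown_genus_excluded(self, backbone):
        membership = {"s1": "g0", "weird": "not-a-genus"}
        out = graft_and_resolve(backbone, membership, seed=0)
        assert "weird" not in {lf.taxon.label for lf in out.leaf_node_iter()}


class TestBranchOccurrences:
    def test_union_rule_three_tips(self):
        occ = np.zeros((3, 4), dtype=bool)
        occ[0, [1, 2]] = True   # A
        occ[1, [2]] = True      # B
        occ[2, [0]] = True      # C
        pm = PresenceMatrix(occ, ["A", "B", "C"])
        feats = branch_occurrences(tree_abc(), pm)
        by_tips = {f.tips: f for f in feats}
        assert by_tips[frozenset({"A", "B"})].cells == frozenset({1, 2})
        assert by_tips[frozenset({"A"})].cells == frozenset({1, 2})
        assert by_tips[frozenset({"B"})].cells == frozenset({2})
        assert by_tips[frozenset({"C"})].cells == frozenset({0})
        assert len(feats) == 4  # root edge excluded

    def test_matches_descendant_enumeration(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            tree = simulate_tree(rng.integers(3, 10), seed=seed)
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            pm = PresenceMatrix(random_presences(rng, len(labels), 12), labels)
            feats = {f.tips: f.cells for f in branch_occurrences(tree, pm)}
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                tips = frozenset(descendant_tips(tree, node))
                expect = set()
                for t in tips:
                    expect |= set(pm.cells_of(t).tolist())
                assert feats[tips] == frozenset(expect)

    def test_ancestor_contains_descendant_cells(self, small_landscape):
        feats = branch_occurrences(small_landscape.tree, small_landscape.presences)
        by_tips = {f.tips: f.cells for f in feats}
        for tips, cells in by_tips.items():
            for other, ocells in by_tips.items():
                if other < tips:
                    assert ocells <= cells

    def test_missing_tip_rejected(self):
        pm = PresenceMatrix(np.ones((2, 3), dtype=bool), ["A", "B"])
        with pytest.raises(ValueError, match="C"):
            branch_occurrences(tree_abc(), pm)


class TestFaithPD:
    def test_worked_three_tip_example(self):
        occ = np.zeros((3, 3), dtype=bool)
        occ[0, 0] = True                  # cell 0: {A}
        occ[0, 1] = occ[1, 1] = True      # cell 1: {A, B}
        occ[:, 2] = True                  # cell 2: {A, B, C}
        pm = PresenceMatrix(occ, ["A", "B", "C"])
        pd = faith_pd_per_cell(tree_abc(), pm)
        assert pd == pytest.approx([2.0, 3.0, 5.0])

    def test_empty_cell_zero(self):
        occ = np.zeros((3, 2), dtype=bool)
        occ[0, 0] = True
        pm = PresenceMatrix(occ, ["A", "B", "C"])
        pd = faith_pd_per_cell(tree_abc(), pm)
        assert pd[1] == 0.0

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(42)
        for seed in range(30):
            n_tips = int(rng.integers(2, 13))
            tree = simulate_tree(n_tips, seed=seed)
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            pm = PresenceMatrix(random_presences(rng, n_tips, 8), labels)
            pd = faith_pd_per_cell(tree, pm)
            for c in range(8):
                spp = {s for s in labels if c in set(pm.cells_of(s))}
                assert pd[c] == pytest.approx(pd_induced_subtree(tree, spp),
                                              abs=1e-9)

    def test_bounded_by_total_length_and_monotone(self, small_landscape):
        tree, pm = small_landscape.tree, small_landscape.presences
        total = sum(e.length for e in tree.preorder_edge_iter()
                    if e.length is not None)
        pd = faith_pd_per_cell(tree, pm)
        assert (pd <= total + 1e-9).all()
        # dropping a species never increases any cell's PD
        sub = pm.subset(pm.species[1:])
        sub_tree = tree.clone(depth=1)
        sub_tree.retain_taxa_with_labels(pm.species[1:])
        pd_sub = faith_pd_per_cell(sub_tree, sub)
        assert (pd_sub <= pd + 1e-9).all()


class TestCSH:
    def test_arithmetic(self):
        rec = compute_csh(10, 5, unit_id="x")
        assert rec.csh == pytest.approx(-0.5)
        assert rec.label == "contracted"

    def test_lost_and_greatly_expanded(self):
        assert compute_csh(10, 0).label == "lost"
        rec = compute_csh(10, 19)
        assert rec.csh == pytest.approx(0.9)
        assert rec.label == "greatly_expanded"
        assert compute_csh(10, 18).label == "stable"  # csh 0.8 not strict >

    def test_zero_current_flagged(self):
        rec = compute_csh(0, 5)
        assert rec.flagged and np.isnan(rec.csh)

    def test_accepts_binary_ranges(self):
        cur = BinaryRange("sp", frozenset({1, 2}))
        fut = BinaryRange("sp", frozenset({2}), scenario="future-x")
        rec = compute_csh(cur, fut)
        assert rec.unit_id == "sp" and rec.csh == pytest.approx(-0.5)


class TestPDClasses:
    def test_ten_distinct_values_equal_classes(self):
        vals = np.arange(10, dtype=float)
        classes = pd_quantile_classes(vals, 5)
        assert np.bincount(classes)[1:].tolist() == [2, 2, 2, 2, 2]

    def test_monotone_relabel_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.random(40)
        a = pd_quantile_classes(vals, 5)
        b = pd_quantile_classes(np.exp(3 * vals), 5)
        assert np.array_equal(a, b)

    def test_heavy_ties_match_rank_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            vals = rng.integers(0, 4, size=rng.integers(10, 40)).astype(float)
            if np.unique(vals).size == 1:
                continue
            got = pd_quantile_classes(vals, 5)
            assert np.array_equal(got, quantile_classes_by_rank(vals, 5))
            assert set(np.unique(got)) <= set(range(1, 6))

    def test_all_equal_single_class(self):
        assert (pd_quantile_classes(np.ones(10), 5) == 1).all()
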