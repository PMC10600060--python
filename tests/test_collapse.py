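"""Edge collapsing: single histories, whole sDAGs, order invariance, and
equivalence with per-history collapsing."""

import random

import pytest

import histdag as hd
from histdag.collapse import _collapsible, label_predicate
from histdag.core import SDAGNode, UA
from histdag.errors import LeafTargetError, NotAnEdgeError, UAParentError

from conftest import random_sdag

F = hd.hamming_parsimony()


def collapsible_edges(t):
    return [e for e in t.sorted_edges() if _collapsible(*e, label_predicate)]


class TestCollapseEdgeInHistory:
    @pytest.fixture
    def deep_history(self):
        # root (A, {{A,C},{G}}) whose child over {A,C} is (A, {{A},{C}})
        inner = hd.LabeledTree("A", (hd.LabeledTree("A"), hd.LabeledTree("C")))
        return hd.history_from_labeled_tree(
            hd.LabeledTree("A", (inner, hd.LabeledTree("G")))
        )

    def test_collapse_merges_clades(self, deep_history):
        t = deep_history
        parent = t.root
        (child,) = t.children_of_clade(parent, frozenset({"A", "C"}))
        collapsed = hd.collapse_edge_in_history(t, parent, child)
        assert collapsed.root == SDAGNode.make("A", [{"A"}, {"C"}, {"G"}])
        assert len(collapsed.edges) == len(t.edges) - 1
        assert collapsed.validate() == []
        assert collapsed.leaf_labels() == t.leaf_labels()

    def test_leaf_target_rejected(self, deep_history):
        t = deep_history
        leaf = SDAGNode.leaf("G")
        with pytest.raises(LeafTargetError):
            hd.collapse_edge_in_history(t, t.root, leaf)

    def test_ua_parent_rejected(self, deep_history):
        t = deep_history
        with pytest.raises(UAParentError):
            hd.collapse_edge_in_history(t, UA, t.root)

    def test_absent_edge_rejected(self, deep_history):
        t = deep_history
        with pytest.raises(NotAnEdgeError):
            hd.collapse_edge_in_history(t, t.root, SDAGNode.leaf("T"))


class TestCollapseHistory:
    def test_already_collapsed_is_fixed_point(self, cherry):
        assert hd.collapse_history(cherry) == cherry

    def test_sampled_ancestor_edge_survives(self):
        # internal node AA with a leaf child AA: the edge targets a leaf, so
        # it is not collapsible and the structure is already label-collapsed
        t = hd.history_from_labeled_tree(
            hd.LabeledTree("AA", (hd.LabeledTree("AA"), hd.LabeledTree("AC"))),
        )
        assert hd.collapse_history(t) == t

    @pytest.mark.parametrize("seed", range(10))
    def test_order_invariance(self, seed):
        """Collapsing a history's collapsible edges in 10 random orders
        yields identical results."""
        t = hd.random_history(
            hd.SimulationConfig(
                n_leaves=6, sequence_length=4, mutation_rate_per_site=0.08, seed=seed
            )
        )
        reference = hd.collapse_history(t)
        for order_seed in range(10):
            rng = random.Random(order_seed)
            cur = t
            while True:
                options = collapsible_edges(cur)
                if not options:
                    break
                cur = hd.collapse_edge_in_history(cur, *rng.choice(options))
            assert cur == reference

    @pytest.mark.parametrize("seed", range(10))
    def test_collapse_preserves_leaves_and_score(self, seed):
        t = hd.random_history(
            hd.SimulationConfig(
                n_leaves=5, sequence_length=4, mutation_rate_per_site=0.1, seed=seed
            )
        )
        c = hd.collapse_history(t)
        assert c.leaf_labels() == t.leaf_labels()
        assert hd.history_weight(c, F) == hd.history_weight(t, F)
        assert not collapsible_edges(c)


class TestCollapseSdag:
    def test_single_history_sdag(self):
        t = hd.random_history(
            hd.SimulationConfig(
                n_leaves=5, sequence_length=4, mutation_rate_per_site=0.1, seed=3
            )
        )
        d = hd.sdag_union([t])
        assert hd.collapse_sdag(d) == hd.sdag_union([hd.collapse_history(t)])

    def test_already_collapsed_sdag_unchanged(self, four_history_union):
        # no two adjacent non-leaf nodes share a label in this fixture...
        collapsed = hd.collapse_sdag(four_history_union)
        per_history = {
            hd.collapse_history(t) for t in four_history_union.iter_histories()
        }
        assert set(collapsed.iter_histories()) == per_history

    @pytest.mark.parametrize("seed", range(30))
    def test_equivalence_with_per_history_collapse(self, seed):
        d = random_sdag(seed, n_leaves=4 + seed % 2, length=4, n_histories=3)
        assert d.count_histories() <= 1000
        collapsed = hd.collapse_sdag(d)
        assert collapsed.validate() == []
        expected = {hd.collapse_history(t) for t in d.iter_histories()}
        assert set(collapsed.iter_histories()) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_queue_order_invariance(self, seed):
        d = random_sdag(seed + 50, n_leaves=4, length=4, n_histories=3)
        reference = hd.collapse_sdag(d)
        for order_seed in range(5):
            assert hd.collapse_sdag(d, rng=random.Random(order_seed)) == reference

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotence(self, seed):
        d = random_sdag(seed + 80, n_leaves=4, length=4, n_histories=3)
        once = hd.collapse_sdag(d)
        assert hd.collapse_sdag(once) == once

    @pytest.mark.parametrize("seed", range(10))
    def test_leaf_sets_and_scores_preserved(self, seed):
        d = random_sdag(seed + 110, n_leaves=4, length=4, n_histories=2)
        before = sorted(
            hd.history_weight(hd.collapse_history(t), F)
            for t in d.iter_histories()
        )
        collapsed = hd.collapse_sdag(d)
        leaf_sets = {t.leaf_labels() for t in d.iter_histories()}
        assert {t.leaf_labels() for t in collapsed.iter_histories()} == leaf_sets
        after = sorted(
            hd.history_weight(t, F) for t in collapsed.iter_histories()
        )
        # collapsed histories may deduplicate, so compare as sets of scores
        assert set(after) == set(before)

    def test_both_endpoints_may_survive(self):
        """Within an sDAG, both endpoints of a collapsed edge can survive:
        each may retain a parent edge and a full complement of child edges
        through its other (non-collapsible) alternatives."""
        leaves = {x: hd.LabeledTree(x) for x in "ACGT"}

        def build(root_label, mid_label):
            mid = hd.LabeledTree(mid_label, (leaves["A"], leaves["C"]))
            return hd.history_from_labeled_tree(
                hd.LabeledTree(root_label, (mid, leaves["G"], leaves["T"]))
            )

        # the A->A edge is collapsible; vp keeps its pair over {A,C} through
        # the C-labeled sibling, and vc keeps a parent through the C-labeled
        # root, so both endpoints survive the collapse
        d = hd.sdag_union([build("A", "A"), build("A", "C"), build("C", "A")])
        vp = build("A", "A").root
        vc = SDAGNode.make("A", [{"A"}, {"C"}])
        assert (vp, vc) in d.edges
        collapsed = hd.collapse_sdag(d)
        assert (vp, vc) not in collapsed.edges
        assert vp in collapsed.nodes and vc in collapsed.nodes
        expected = {hd.collapse_history(t) for t in d.iter_histories()}
        assert set(collapsed.iter_histories()) == expected
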