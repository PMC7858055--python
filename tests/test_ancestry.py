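import itertools

import dendropy
import numpy as np
import pytest

from replimode import simdata
from replimode.ancestry import (
    TraitTree,
    map_modes_to_tree,
    min_changes,
    read_tree,
)

CLADE_TOPOLOGY = "((cladeI_bi,cladeII_uni),(cladeIII_uni,cladeIV_uni));"
CLADE_STATES = {
    "cladeI_bi": "bi", "cladeII_uni": "uni",
    "cladeIII_uni": "uni", "cladeIV_uni": "uni",
}


def clade_tree():
    return TraitTree(
        tree=dendropy.Tree.get(data=CLADE_TOPOLOGY, schema="newick"),
        tip_states=dict(CLADE_STATES),
    )


def brute_force_min_changes(tree, tip_states, alphabet, root_constraint=None):
    """Independent oracle: enumerate every internal-node labeling."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = float("inf")
    for labels in itertools.product(alphabet, repeat=len(internal)):
        assign = dict(zip((id(n) for n in internal), labels))
        if root_constraint is not None and assign[id(tree.seed_node)] != root_constraint:
            continue
        cost = 0
        ok = True
        for n in internal:
            for child in n.child_nodes():
                if child.is_leaf():
                    label = child.taxon.label.replace(" ", "_")
                    if label not in tip_states:
                        continue
                    child_state = tip_states[label]
                else:
                    child_state = assign[id(child)]
                if assign[id(n)] != child_state:
                    cost += 1
        if ok:
            best = min(best, cost)
    return best


def fitch_count(tree, tip_states):
    """Fitch small parsimony for binary trees (unit cost), bottom-up."""
    count = 0

    def sets(node):
        nonlocal count
        if node.is_leaf():
            return {tip_states[node.taxon.label.replace(" ", "_")]}
        children = [sets(c) for c in node.child_nodes()]
        inter = set.intersection(*children)
        if inter:
            return inter
        count += len(children) - 1
        return set.union(*children)

    sets(tree.seed_node)
    return count


def random_tree_and_states(rng, n_tips):
    labels = [f"t{i}" for i in range(n_tips)]
    parts = list(labels)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    tree = dendropy.Tree.get(data=parts[0] + ";", schema="newick")
    states = {lab: ("uni", "bi")[rng.integers(2)] for lab in labels}
    return tree, states


class TestCladeArgument:
    def test_uni_root_needs_one_change(self):
        res = min_changes(clade_tree(), "uni")
        assert res.min_changes == 1

    def test_bi_root_needs_two_changes(self):
        res = min_changes(clade_tree(), "bi")
        assert res.min_changes == 2

    def test_unconstrained_equals_best_constraint(self):
        tt = clade_tree()
        res = min_changes(tt)
        assert res.min_changes == min(
            min_changes(tt, s).min_changes for s in tt.alphabet
        )

    def test_constant_character_needs_no_change(self):
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        tt = TraitTree(tree=tree, tip_states={t: "uni" for t in "abcd"})
        assert min_changes(tt, "uni").min_changes == 0

    def test_change_edges_located_on_bi_clade_branch(self):
        res = min_changes(clade_tree(), "uni")
        assert len(res.change_edges) == 1


class TestSankoffCorrectness:
    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n_tips = int(rng.integers(4, 9))
            tree, states = random_tree_and_states(rng, n_tips)
            tt = TraitTree(tree=tree, tip_states=states)
            for constraint in (None, "uni", "bi"):
                expected = brute_force_min_changes(
                    tree, states, ("uni", "bi"), constraint
                )
                assert min_changes(tt, constraint).min_changes == expected

    def test_matches_fitch_on_binary_trees(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tree, states = random_tree_and_states(rng, int(rng.integers(4, 10)))
            tt = TraitTree(tree=tree, tip_states=states)
            assert min_changes(tt).min_changes == fitch_count(tree, states)

    def test_reroot_invariance_unconstrained(self):
        rng = np.random.default_rng(2)
        tree, states = random_tree_and_states(rng, 8)
        base = min_changes(TraitTree(tree=tree, tip_states=states)).min_changes
        for edge_node in list(tree.preorder_node_iter())[2:5]:
            t2 = tree.clone(depth=1)
            target = [
                n for n in t2.preorder_node_iter()
                if n.level() == edge_node.level()
            ][0]
            if target.edge.tail_node is None:
                continue
            t2.reroot_at_edge(target.edge)
            moved = min_changes(TraitTree(tree=t2, tip_states=states)).min_changes
            assert moved == base

    def test_multifurcation_handled(self):
        tree = dendropy.Tree.get(data="(a,b,c,(d,e));", schema="newick")
        states = {"a": "uni", "b": "uni", "c": "bi", "d": "bi", "e": "bi"}
        tt = TraitTree(tree=tree, tip_states=states)
        expected = brute_force_min_changes(tree, states, ("uni", "bi"))
        assert min_changes(tt).min_changes == expected

    def test_missing_tip_errors_with_name(self):
        tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
        tt = TraitTree(tree=tree, tip_states={"a": "uni", "b": "bi"})
        with pytest.raises(ValueError, match="c"):
            min_changes(tt)

    def test_unknown_state_symbol_errors(self):
        tree = dendropy.Tree.get(data="(a,b);", schema="newick")
        with pytest.raises(ValueError, match="sideways"):
            TraitTree(tree=tree, tip_states={"a": "uni", "b": "sideways"})

    def test_unknown_root_constraint_errors(self):
        with pytest.raises(ValueError):
            min_changes(clade_tree(), "sideways")


class TestSimulatedTreeTruth:
    def test_planted_clade_counts_recovered(self):
        for seed in range(5):
            tree, states, truth = simdata.generate_trait_tree(
                n_tips=10, topology_seed=seed, bi_clade_size=3
            )
            tt = TraitTree(tree=tree, tip_states=states)
            assert (
                min_changes(tt, "uni").min_changes
                == truth["min_changes_uni_root"]
            )


class TestMapModesToTree:
    def test_complete_mapping(self):
        tree = read_tree("((a,b),(c,d));")
        calls = {"a": "bidirectional", "b": "unidirectional",
                 "c": "unidirectional", "d": "unidirectional"}
        tt = map_modes_to_tree(tree, calls)
        assert tt.tip_states == {"a": "bi", "b": "uni", "c": "uni", "d": "uni"}

    def test_unpredictable_becomes_missing(self):
        tree = read_tree("((a,b),(c,d));")
        calls = {"a": "bidirectional", "b": "unpredictable",
                 "c": "unidirectional", "d": "unidirectional"}
        tt = map_modes_to_tree(tree, calls)
        assert "b" not in tt.tip_states
        assert min_changes(tt, "uni").min_changes == 1

    def test_disjoint_names_error(self):
        tree = read_tree("((a,b),(c,d));")
        with pytest.raises(ValueError):
            map_modes_to_tree(tree, {"x": "uni", "y": "uni"})
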