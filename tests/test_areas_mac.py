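"""MAC parsimony: Sankoff DP against exhaustive enumeration."""

import itertools

import numpy as np
import pytest

from primdiv import (
    AreaSystem,
    enumerate_states,
    mac_change_bounds,
    mac_cost,
    mac_reconstruct,
    parse_newick,
)

from conftest import random_topology_newick


def brute_force(tree, tips, states):
    """Exhaustive minimum over all internal-state assignments (vectorized).

    Returns (min_cost, per-node optimal state sets, (min_gains, max_gains)).
    """
    t = tree.dendropy_tree
    internal = [n for n in t.preorder_node_iter() if not n.is_leaf()]
    pos = {n: i for i, n in enumerate(internal)}
    n_s = len(states)
    cost_m = np.array([[mac_cost(s, u) for u in states] for s in states])
    gain_m = np.array(
        [[bin(u & ~s).count("1") for u in states] for s in states]
    )
    assign = np.array(
        list(itertools.product(range(n_s), repeat=len(internal))), dtype=np.int16
    )
    total = np.zeros(len(assign), dtype=np.int64)
    gains = np.zeros(len(assign), dtype=np.int64)
    for node in internal:
        for child in node.child_nodes():
            pi = assign[:, pos[node]]
            if child.is_leaf():
                obs = tips[child.taxon.label]
                ccost = np.array([mac_cost(s, obs) for s in states])
                cgain = np.array([bin(obs & ~s).count("1") for s in states])
                total += ccost[pi]
                gains += cgain[pi]
            else:
                ci = assign[:, pos[child]]
                total += cost_m[pi, ci]
                gains += gain_m[pi, ci]
    mn = int(total.min())
    at_min = total == mn
    node_sets = {
        node: frozenset(states[j] for j in np.unique(assign[at_min, pos[node]]))
        for node in internal
    }
    return mn, node_sets, (int(gains[at_min].min()), int(gains[at_min].max()))


class TestCost:
    def test_identity_zero(self, areas4):
        m = areas4.mask(["Asia"])
        assert mac_cost(m, m) == 0

    def test_single_gain(self, areas4):
        assert mac_cost(areas4.mask("Asia"), areas4.mask(["Asia", "Africa"])) == 1

    def test_two_losses_one_gain(self, areas4):
        assert (
            mac_cost(areas4.mask(["Asia", "Africa"]), areas4.mask("Madagascar")) == 3
        )

    def test_symmetric_triangle(self, areas4, rng):
        states = enumerate_states(areas4)
        for _ in range(50):
            a, b, c = (states[i] for i in rng.integers(len(states), size=3))
            assert mac_cost(a, b) == mac_cost(b, a)
            assert mac_cost(a, c) <= mac_cost(a, b) + mac_cost(b, c)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mac_cost(0, 1)


class TestEnumerateStates:
    @pytest.mark.parametrize(
        "n_areas,max_range,expected", [(4, 2, 10), (6, 2, 21), (3, 3, 7), (5, 1, 5)]
    )
    def test_counts(self, n_areas, max_range, expected):
        sys_ = AreaSystem(tuple(f"a{i}" for i in range(n_areas)), max_range)
        states = enumerate_states(sys_)
        assert len(states) == expected
        # deterministic order: cardinality then bitmask
        keys = [(bin(s).count("1"), s) for s in states]
        assert keys == sorted(keys)


class TestReconstruct:
    def test_uniform_tips_zero_changes(self, areas4, three_tip_tree):
        asia = areas4.mask("Asia")
        res = mac_reconstruct(three_tip_tree, dict.fromkeys("ABC", asia), areas4)
        assert res.min_total_changes == 0
        assert all(ss == {asia} for ss in res.node_states.values())
        assert mac_change_bounds(res) == (0, 0, 0, 0)

    def test_cherry_with_outgroup_exhaustively(self, areas4, three_tip_tree):
        tips = {
            "A": areas4.mask("Asia"),
            "B": areas4.mask("Africa"),
            "C": areas4.mask("Asia"),
        }
        res = mac_reconstruct(three_tip_tree, tips, areas4)
        mn, node_sets, grange = brute_force(
            three_tip_tree, tips, enumerate_states(areas4)
        )
        assert res.min_total_changes == mn
        for node, ss in node_sets.items():
            assert res.node_states[node] == ss
        assert res.gains_range == grange

    def test_uncoded_tip_listed(self, areas4, three_tip_tree):
        with pytest.raises(ValueError, match="C"):
            mac_reconstruct(
                three_tip_tree, {"A": 1, "B": 1}, areas4
            )

    @pytest.mark.parametrize("n_tips", [4, 5, 6])
    def test_matches_brute_force_on_random_instances(self, areas4, rng, n_tips):
        states = enumerate_states(areas4)
        for _ in range(17):  # ~50 instances across the three sizes
            tree = parse_newick(random_topology_newick(rng, n_tips))
            tips = {
                lab: states[rng.integers(len(states))] for lab in tree.tip_labels
            }
            res = mac_reconstruct(tree, tips, areas4)
            mn, node_sets, grange = brute_force(tree, tips, states)
            assert res.min_total_changes == mn
            assert res.gains_range == grange
            assert res.losses_range == (mn - grange[1], mn - grange[0])
            for node, ss in node_sets.items():
                assert res.node_states[node] == ss

    def test_matches_brute_force_eight_tips(self, rng):
        # smaller state space (3 areas) keeps 7 internal nodes enumerable
        sys3 = AreaSystem(("Africa", "Madagascar", "Asia"), max_range_size=2)
        states = enumerate_states(sys3)
        for _ in range(3):
            tree = parse_newick(random_topology_newick(rng, 8))
            tips = {
                lab: states[rng.integers(len(states))] for lab in tree.tip_labels
            }
            res = mac_reconstruct(tree, tips, sys3)
            mn, _, grange = brute_force(tree, tips, states)
            assert res.min_total_changes == mn
            assert res.gains_range == grange

    def test_multifurcating_tree_accepted(self, areas4):
        tree = parse_newick("(A:1,B:1,C:1,D:1);", require_ultrametric=False)
        tips = {
            "A": areas4.mask("Asia"),
            "B": areas4.mask("Asia"),
            "C": areas4.mask("Africa"),
            "D": areas4.mask("Africa"),
        }
        res = mac_reconstruct(tree, tips, areas4)
        # root Asia: two 2-change tip edges; Africa symmetric; {Asia,Africa}:
        # four 1-change edges — all cost 4
        assert res.min_total_changes == 4
        root = tree.dendropy_tree.seed_node
        assert res.node_states[root] == {
            areas4.mask("Asia"),
            areas4.mask("Africa"),
            areas4.mask(["Asia", "Africa"]),
        }


class TestFitchEquivalence:
    def test_single_area_mac_is_twice_fitch(self, rng):
        """With max_range_size=1 each area switch is one loss plus one gain,
        so the MAC minimum equals exactly twice the Fitch change count."""
        sys1 = AreaSystem(("a", "b", "c", "d"), max_range_size=1)
        states = enumerate_states(sys1)

        def fitch(tree, tips):
            changes = 0
            sets = {}
            for node in tree.dendropy_tree.postorder_node_iter():
                if node.is_leaf():
                    sets[node] = {tips[node.taxon.label]}
                    continue
                c1, c2 = (sets[c] for c in node.child_nodes())
                inter = c1 & c2
                if inter:
                    sets[node] = inter
                else:
                    sets[node] = c1 | c2
                    changes += 1
            return changes

        for _ in range(20):
            tree = parse_newick(random_topology_newick(rng, 8))
            tips = {
                lab: states[rng.integers(len(states))] for lab in tree.tip_labels
            }
            res = mac_reconstruct(tree, tips, sys1)
            assert res.min_total_changes == 2 * fitch(tree, tips)
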