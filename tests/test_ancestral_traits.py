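"""Binary trait reconstruction: pruning likelihood, posteriors, MPPA."""

import numpy as np
import pytest

from phylomod.ancestral_traits import (TraitTable, annotate_leaves,
                                       ancestral_binary_ml, reconstruct_traits,
                                       _log_likelihood, _mppa_call)
from phylomod.synthetic import simulate_binary_trait
from phylomod.trees import parse_newick, label_internal_nodes, node_label
from oracles import trait_likelihood_bruteforce, random_tree_newick


def tree_from(text):
    return label_internal_nodes(parse_newick(text))


class TestAnnotateLeaves:
    def test_focal_leaf_statuses(self):
        table, added = annotate_leaves(
            [("hs1", "ACAN"), ("hs1", "VCAN")],
            focal_leaves=["hs1"],
            all_partners=["ACAN", "VCAN", "LRP1"],
            all_leaves=["hs1", "mm1"],
        )
        assert table.status[("hs1", "ACAN")] == "1"
        assert table.status[("hs1", "VCAN")] == "1"
        assert table.status[("hs1", "LRP1")] == "0"
        assert added == []

    def test_non_focal_leaves_all_missing(self):
        table, _ = annotate_leaves(
            [("hs1", "ACAN")], ["hs1"], ["ACAN"], ["hs1", "mm1", "dr1"]
        )
        for leaf in ("mm1", "dr1"):
            assert table.status[(leaf, "ACAN")] == "?"

    def test_unlisted_partner_added_and_reported(self):
        table, added = annotate_leaves(
            [("hs1", "NEW")], ["hs1"], ["ACAN"], ["hs1"]
        )
        assert added == ["NEW"]
        assert table.status[("hs1", "NEW")] == "1"

    def test_unknown_leaf_raises(self):
        with pytest.raises(KeyError):
            annotate_leaves([("ghost", "ACAN")], ["hs1"], ["ACAN"], ["hs1"])


class TestPruning:
    def test_likelihood_matches_joint_summation(self):
        rng = np.random.default_rng(23)
        for _ in range(4):
            tree = tree_from(random_tree_newick(6, rng))
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            states = {
                l: rng.choice([0, 1, None], p=[0.4, 0.4, 0.2])
                for l in leaves
            }
            if all(s is None for s in states.values()):
                states[leaves[0]] = 1
            states = {l: (None if s is None else int(s))
                      for l, s in states.items()}
            pi1, rate = 0.3, 0.7
            pi = np.array([1 - pi1, pi1])
            loglik = _log_likelihood(tree, states, pi, rate)
            total, post = trait_likelihood_bruteforce(tree, states, pi1, rate)
            assert loglik == pytest.approx(np.log(total), abs=1e-9)
            rec = ancestral_binary_ml(tree, states, pi1=pi1, rate=rate)
            for node in tree.preorder_node_iter():
                label = node_label(node)
                if node.is_leaf() and states[label] is not None:
                    continue  # observed leaves are pinned to their state
                assert rec.posterior1[label] == pytest.approx(
                    post[label], abs=1e-9
                )

    def test_two_leaf_symmetric_star_root_posterior_half(self):
        tree = tree_from("(A:1,B:1);")
        rec = ancestral_binary_ml(tree, {"A": 1, "B": 0}, pi1=0.5, rate=1.0)
        assert rec.posterior1["G1"] == pytest.approx(0.5, abs=1e-12)
        assert rec.calls["G1"] == frozenset({0, 1})
        assert "G1" not in rec.present_nodes()

    def test_posteriors_are_probabilities(self):
        rng = np.random.default_rng(5)
        tree = tree_from(random_tree_newick(6, rng))
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        states = {l: int(i % 2 == 0) for i, l in enumerate(leaves)}
        rec = ancestral_binary_ml(tree, states)
        for p in rec.posterior1.values():
            assert 0.0 <= p <= 1.0

    def test_all_ones_calls_one_everywhere(self):
        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        states = {"A": 1, "B": 1, "C": None, "D": 1}
        rec = ancestral_binary_ml(tree, states)
        assert all(c == frozenset({1}) for c in rec.calls.values())

    def test_all_missing_raises(self):
        tree = tree_from("(A:1,B:1);")
        with pytest.raises(ValueError, match="unobserved"):
            ancestral_binary_ml(tree, {"A": None, "B": None})

    def test_observed_leaves_never_overwritten(self):
        tree = tree_from("((A:0.01,B:0.01):0.01,C:5);")
        # C disagrees with the tight (A, B) cherry
        rec = ancestral_binary_ml(tree, {"A": 1, "B": 1, "C": 0})
        assert rec.posterior1["A"] == 1.0
        assert rec.posterior1["C"] == 0.0
        assert rec.calls["C"] == frozenset({0})


class TestMppaCall:
    @pytest.mark.parametrize("p1,expected", [
        (0.9, {1}), (0.76, {1}), (0.74, {0, 1}), (0.5, {0, 1}),
        (0.26, {0, 1}), (0.24, {0}), (0.05, {0}),
    ])
    def test_brier_optimal_binary_rule(self, p1, expected):
        assert _mppa_call(p1) == frozenset(expected)


class TestReconstructTraits:
    def test_in_map_collects_unambiguous_presence(self):
        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        table = TraitTable(
            traits=["t1", "t2"],
            status={
                ("A", "t1"): "1", ("B", "t1"): "1",
                ("C", "t1"): "0", ("D", "t1"): "0",
                ("A", "t2"): "0", ("B", "t2"): "0",
                ("C", "t2"): "0", ("D", "t2"): "1",
            },
            leaves=["A", "B", "C", "D"],
        )
        in_map, recons = reconstruct_traits(tree, table)
        assert in_map["A"] == {"t1"}
        assert in_map["D"] == {"t2"}
        assert recons["t2"].single_carrier

    def test_simulated_states_recovered_at_most_nodes(self):
        """Under rate x mean-branch-length <= 0.2, reconstruction matches
        the simulated ancestral states at >= 85% of internal nodes over
        20 seeds: the marginal-posterior best state agrees with the truth,
        and the (set-valued) MPPA call is compatible with the truth —
        MPPA deliberately leaves genuinely uncertain nodes ambiguous, so
        ambiguity is scored as compatible, not as a strict match."""
        # balanced 64-leaf tree, all branches 0.2, rate 1.0
        def balanced(n):
            names = [f"t{i}" for i in range(n)]

            def build(lo, hi):
                if hi - lo == 1:
                    return names[lo] + ":0.2"
                mid = (lo + hi) // 2
                return f"({build(lo, mid)},{build(mid, hi)}):0.2"

            return build(0, n) + ";"

        tree = tree_from(balanced(64))
        best_state_acc = []
        compatible_acc = []
        for seed in range(20):
            leaf_states, node_states = simulate_binary_trait(
                tree, pi1=0.5, rate=1.0, seed=seed
            )
            if len(set(leaf_states.values())) == 1:
                continue
            rec = ancestral_binary_ml(tree, leaf_states)
            internal = [
                node_label(n) for n in tree.preorder_node_iter()
                if not n.is_leaf()
            ]
            best_state_acc.append(np.mean([
                (rec.posterior1[lab] >= 0.5) == node_states[lab]
                for lab in internal
            ]))
            compatible_acc.append(np.mean([
                node_states[lab] in rec.calls[lab] for lab in internal
            ]))
        assert np.mean(best_state_acc) >= 0.85
        assert np.mean(compatible_acc) >= 0.85
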