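"""Single-gain (Dollo) inference of integration branches and relative order."""

from __future__ import annotations

import numpy as np
import pytest

from coopte.phylo import (
    call_presence_from_identity,
    infer_gain,
    infer_gains,
    integration_order,
)

from _oracles import dollo_exhaustive, order_by_path_comparison
from conftest import mammal_tree, random_rooted_tree


class TestInferGain:
    def test_present_everywhere_gains_at_root_no_losses(self):
        tree = mammal_tree()
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        a = infer_gain({sp: True for sp in leaves}, tree, element="AmnSINE1")
        assert a.clade_name == "Mammalia"
        assert a.n_losses == 0

    def test_placental_only_pattern_gains_on_eutherian_stem(self):
        tree = mammal_tree()
        presence = {"platypus": False, "opossum": False,
                    "mouse": True, "human": True}
        a = infer_gain(presence, tree, element="MER117")
        assert a.clade_name == "Eutheria"
        assert a.n_losses == 0

    def test_loss_inside_gain_clade_is_counted(self):
        tree = mammal_tree()
        presence = {"platypus": True, "opossum": True,
                    "mouse": True, "human": False}
        a = infer_gain(presence, tree)
        assert a.clade_name == "Mammalia"
        assert a.n_losses == 1

    def test_single_present_species_gains_on_that_leaf(self):
        a = infer_gain({"mouse": True, "human": False}, mammal_tree())
        assert a.clade_name == "mouse"
        assert a.n_losses == 0

    def test_absent_everywhere_is_an_error(self):
        with pytest.raises(ValueError, match="absent everywhere"):
            infer_gain({"mouse": False}, mammal_tree(), element="X")

    def test_unknown_species_error_names_it(self):
        with pytest.raises(ValueError, match="axolotl"):
            infer_gain({"axolotl": True}, mammal_tree())

    def test_matches_exhaustive_enumeration_on_random_trees(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 11))
            tree = random_rooted_tree(rng, n)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            k = int(rng.integers(1, n + 1))
            present = set(rng.choice(leaves, size=k, replace=False))
            presence = {sp: sp in present for sp in leaves}
            got = infer_gain(presence, tree)
            node, losses = dollo_exhaustive(tree, present)
            assert got.gain_node is node
            assert got.n_losses == losses

    def test_losses_zero_iff_all_descendants_present(self, rng):
        for _ in range(50):
            tree = random_rooted_tree(rng, int(rng.integers(2, 9)))
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            k = int(rng.integers(1, len(leaves) + 1))
            present = set(rng.choice(leaves, size=k, replace=False))
            a = infer_gain({sp: sp in present for sp in leaves}, tree)
            descendants = {l.taxon.label for l in a.gain_node.leaf_iter()}
            assert (a.n_losses == 0) == (descendants == present)
            assert present <= descendants  # gain covers every presence


class TestIntegrationOrder:
    def test_nested_clades_give_strict_order(self):
        tree = mammal_tree()
        rows = {
            "AmnSINE1": {"platypus": True, "opossum": True, "mouse": True,
                         "human": True},
            "X6b_DNA": {"platypus": False, "opossum": True, "mouse": True,
                        "human": True},
            "MER117": {"platypus": False, "opossum": False, "mouse": True,
                       "human": True},
        }
        assignments = [infer_gain(v, tree, element=k) for k, v in rows.items()]
        order = integration_order(assignments, tree)
        assert order == [["AmnSINE1"], ["X6b_DNA"], ["MER117"]]

    def test_equal_gain_nodes_form_one_tie_group(self):
        tree = mammal_tree()
        presence = {"mouse": True, "human": True,
                    "platypus": False, "opossum": False}
        a = infer_gain(presence, tree, element="a")
        b = infer_gain(presence, tree, element="b")
        assert integration_order([a, b], tree) == [["a", "b"]]

    def test_sister_clades_are_not_ordered(self):
        tree = mammal_tree()
        a = infer_gain({"mouse": True}, tree, element="rodent_only")
        b = infer_gain({"human": True}, tree, element="primate_only")
        assert integration_order([a, b], tree) == [
            ["primate_only", "rodent_only"]
        ]

    def test_matches_path_comparison_oracle_on_random_inputs(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 10))
            tree = random_rooted_tree(rng, n)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            assignments = []
            for e in range(int(rng.integers(1, 6))):
                k = int(rng.integers(1, n + 1))
                present = set(rng.choice(leaves, size=k, replace=False))
                assignments.append(
                    infer_gain({sp: sp in present for sp in leaves}, tree,
                               element=f"e{e}")
                )
            assert integration_order(assignments, tree) == \
                order_by_path_comparison(assignments)


class TestCallPresence:
    def test_threshold_is_inclusive(self):
        calls = call_presence_from_identity(
            {"human": 71.4, "platypus": 65.0, "opossum": 60.0, "frog": 59.9}
        )
        assert calls == {"human": True, "platypus": True,
                         "opossum": True, "frog": False}

    def test_all_zero_identities_give_all_absent(self):
        calls = call_presence_from_identity({"a": 0.0, "b": 0.0})
        assert not any(calls.values())

    def test_presence_monotone_in_threshold(self, rng):
        for _ in range(30):
            table = {
                f"s{i}": float(rng.uniform(0, 100)) for i in range(8)
            }
            prev = None
            for thr in (0, 20, 40, 60, 80, 100):
                n = sum(call_presence_from_identity(table, thr).values())
                if prev is not None:
                    assert n <= prev
                prev = n

    def test_out_of_range_identity_is_an_error(self):
        with pytest.raises(ValueError):
            call_presence_from_identity({"a": 104.0})


def test_infer_gains_runs_over_matrix(rng):
    import numpy as np
    from coopte.model import PresenceMatrix

    tree = mammal_tree()
    m = PresenceMatrix(
        species=["platypus", "opossum", "mouse", "human"],
        elements=["x", "y"],
        present=np.array([[1, 1, 1, 1], [0, 0, 1, 1]], dtype=bool),
    )
    a, b = infer_gains(m, tree)
    assert (a.element, a.clade_name) == ("x", "Mammalia")
    assert (b.element, b.clade_name) == ("y", "Eutheria")
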