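"""Representation, validation and the joint-probability oracle."""

import itertools

import numpy as np
import pytest

from clldbn.core import (
    ConditionalProbabilityTable,
    SlicedRef,
    Variable,
    joint_probability,
    parents_of,
    topological_order,
    validate_network,
)
from clldbn.netdoc import dumps, loads, network_from_dict, network_to_dict
from clldbn.networks._build import NetworkBuilder

from conftest import make_chain_net, make_deterministic_net, make_single_var_net


class TestVariable:
    def test_rejects_single_state(self):
        with pytest.raises(ValueError, match=">=2 states"):
            Variable("X", ("only",))

    def test_rejects_duplicate_states(self):
        with pytest.raises(ValueError, match="duplicate"):
            Variable("X", ("a", "a"))

    def test_state_order_is_significant(self):
        v = Variable("X", ("b", "a"))
        assert v.state_index("b") == 0 and v.state_index("a") == 1


class TestSlicedRef:
    @pytest.mark.parametrize("offset", [-2, 1, 5])
    def test_higher_order_offsets_rejected(self, offset):
        with pytest.raises(ValueError, match="first-order Markov"):
            SlicedRef("X", offset)


class TestValidateNetwork:
    def test_valid_toy_net(self):
        assert validate_network(make_chain_net()).is_valid

    def test_row_sum_violation(self):
        net = make_chain_net()
        net.prior.cpts["A"].table[()] = (0.5, 0.4)
        report = validate_network(net)
        assert not report.is_valid
        assert any("row sum 0.9" in v for v in report.violations)

    def test_missing_parent_combination(self):
        net = make_chain_net()
        del net.prior.cpts["B"].table[("no",)]
        report = validate_network(net)
        assert any("missing parent assignment" in v for v in report.violations)

    def test_intra_slice_cycle(self):
        b = NetworkBuilder("cyclic")
        b.variable("A", ("y", "n"))
        b.variable("B", ("y", "n"))
        rows = {("y",): (0.5, 0.5), ("n",): (0.5, 0.5)}
        b.prior_cpt("A", [("B", 0)], rows)
        b.prior_cpt("B", [("A", 0)], rows)
        b.transition_cpt("A", [], {(): (0.5, 0.5)})
        b.transition_cpt("B", [], {(): (0.5, 0.5)})
        report = validate_network(b.build())
        assert any("cycle" in v for v in report.violations)

    def test_dangling_reference(self):
        net = make_chain_net()
        net.transition.cpts["B"] = ConditionalProbabilityTable(
            "B", (SlicedRef("Ghost", -1),), {("x",): (0.5, 0.5)}
        )
        report = validate_network(net)
        assert any("dangling" in v for v in report.violations)

    def test_negative_probability(self):
        net = make_chain_net()
        net.prior.cpts["A"].table[()] = (1.2, -0.2)
        report = validate_network(net)
        assert any("negative" in v for v in report.violations)

    def test_outcome_independent_of_variable_order(self, hsn):
        doc = network_to_dict(hsn)
        doc["variables"] = list(reversed(doc["variables"]))
        doc["prior"]["cpts"] = list(reversed(doc["prior"]["cpts"]))
        shuffled = network_from_dict(doc)
        assert validate_network(shuffled).is_valid


class TestParentsOf:
    def test_hsn_cll_stage_printed_header(self, hsn):
        refs = parents_of(hsn, "CLL stage", "transition")
        assert [(r.var, r.offset) for r in refs] == [
            ("Prognosis", -1),
            ("CLL stage", -1),
            ("CLL transformation", 0),
        ]

    def test_ten_treatment_result_printed_header(self, ten):
        refs = parents_of(ten, "Treatment result", "transition")
        assert [(r.var, r.offset) for r in refs] == [("Treatment", -1), ("Survival", -1)]

    def test_root_node_has_no_parents(self):
        assert parents_of(make_chain_net(), "A", "prior") == ()

    def test_unknown_variable(self, hsn):
        with pytest.raises(KeyError):
            parents_of(hsn, "Nonexistent", "transition")


class TestTopologicalOrder:
    def test_chain_order_forced(self):
        order = topological_order(make_chain_net(), 2)
        assert order == [("A", 0), ("B", 0), ("A", 1), ("B", 1)]

    def test_parents_precede_children_on_hsn(self, hsn):
        order = topological_order(hsn, 1)
        assert len(order) == 16 and len(set(order)) == 16
        pos = {node: i for i, node in enumerate(order)}
        from clldbn.core import unrolled_parents

        for name, t in order:
            for parent in unrolled_parents(hsn, name, t):
                assert pos[parent] < pos[(name, t)]

    def test_zero_slices_rejected(self):
        with pytest.raises(ValueError):
            topological_order(make_chain_net(), 0)


class TestJointProbability:
    def test_degenerate_deterministic_net(self):
        net = make_deterministic_net()
        assignment = {("A", 0): "a1", ("B", 0): "b0", ("A", 1): "a1", ("B", 1): "b0"}
        assert joint_probability(net, assignment) == 1.0

    def test_hand_product_single_variable(self):
        net = make_single_var_net(p_yes=0.3, p_stay_yes=0.9)
        assert joint_probability(net, {("X", 0): "yes", ("X", 1): "yes"}) == pytest.approx(
            0.27, abs=1e-15
        )

    def test_incomplete_assignment_rejected(self):
        net = make_chain_net()
        with pytest.raises(ValueError, match="missing"):
            joint_probability(net, {("A", 0): "yes"})

    def test_unknown_state_rejected(self):
        net = make_chain_net()
        with pytest.raises(KeyError):
            joint_probability(net, {("A", 0): "maybe", ("B", 0): "yes"})

    def test_normalization_over_full_assignment_space(self):
        net = make_chain_net()
        T = 2
        keys = [(n, t) for t in range(T + 1) for n in net.variables]
        total = sum(
            joint_probability(net, dict(zip(keys, states)))
            for states in itertools.product(*[net.variable(n).states for n, _ in keys])
        )
        assert total == pytest.approx(1.0, abs=1e-8)


class TestSerialization:
    def test_round_trip_preserves_structure_and_values(self):
        net = make_chain_net()
        back = loads(dumps(net))
        assert list(back.variables) == list(net.variables)
        for name in net.variables:
            assert back.variable(name).states == net.variable(name).states
            assert back.transition.cpts[name].table == net.transition.cpts[name].table

    def test_write_read_write_is_stable(self, hsn, ten):
        for net in (hsn, ten):
            once = dumps(net)
            assert dumps(loads(once)) == once

    def test_json_documents_also_parse(self, tmp_path):
        import json

        from clldbn.netdoc import read_network

        net = make_chain_net()
        path = tmp_path / "chain.json"
        path.write_text(json.dumps(network_to_dict(net)))
        assert validate_network(read_network(path)).is_valid
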