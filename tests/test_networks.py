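"""The shipped HSN and TEN definitions: catalogs, printed CPTs, presets."""

import numpy as np
import pytest

from clldbn.core import validate_network
from clldbn.netdoc import dumps
from clldbn.networks import (
    NETWORK_NAMES,
    cpt_coverage_report,
    load_network,
    network_path,
    scenario_preset,
)
from clldbn.inference import predict_marginals


def norm(s: str) -> str:
    return " ".join(s.split()).lower()


# node -> state space, as catalogued for the Health Status Network
HSN_CATALOG = {
    "Age": ["≤ 65 years", "> 65 years"],
    "Autoimmune complications": ["yes", "no"],
    "CLL stage": ["III–IV", "I–II", "0"],  # printed CPT column order
    "CLL transformation": ["yes", "no"],
    "Death": ["yes", "no"],
    "Death from CLL transformation": ["yes", "no"],
    "Death from infections": ["yes", "no"],
    "Death from other cancers": ["yes", "no"],
    "Death from other causes": ["yes", "no"],
    "Endurance": ["yes", "no"],
    "Health": ["ECOG 0–2", "ECOG 3–4"],
    "Infections": ["yes", "no"],
    "Other cancers": ["yes", "no"],
    "Prognosis": ["Good", "Intermediate", "Poor"],
    "Sex": ["Female", "Male"],
    "Survival": ["yes", "no"],
}

# node -> state space for the Treatment Effect Network
TEN_CATALOG = {
    "Age": ["≤ 65 years", "> 65 years"],
    "Break between treatments": ["≤ 6 months", "> 6 months"],
    "CLL stage": ["0", "I–II", "III–IV"],
    "Complications": ["yes", "no"],
    "Death from complications": ["yes", "no"],
    "Death from treatment": ["yes", "no"],
    "Decision": ["Treatment", "Watch and wait", "Death"],
    "Endurance": ["yes", "no"],
    "Health": ["ECOG 0–2", "ECOG 3–4"],
    "Patient's state": ["Good", "Poor"],
    "Previous treatment": ["None", "AA", "PA", "MA"],
    "Previous treatment result": ["CR+PR", "SD", "PD", "Death"],
    "Prognosis": ["Good", "Intermediate", "Poor"],
    "Progression": ["yes", "no"],
    "Sex": ["Female", "Male"],
    "Survival": ["yes", "no"],
    "Treatment": ["None", "AA", "PA", "MA"],
    "Treatment result": ["CR+PR", "SD", "PD", "Death"],
}


class TestCatalogs:
    def test_hsn_has_16_nodes_with_expected_states(self, hsn):
        assert hsn.n_variables == 16
        for name, states in HSN_CATALOG.items():
            got = [norm(s) for s in hsn.variable(name).states]
            assert got == [norm(s) for s in states], name

    def test_ten_has_18_nodes_with_expected_states(self, ten):
        assert ten.n_variables == 18
        for name, states in TEN_CATALOG.items():
            got = [norm(s) for s in ten.variable(name).states]
            assert got == [norm(s) for s in states], name

    def test_shipped_documents_validate(self):
        for name in NETWORK_NAMES:
            assert validate_network(load_network(name)).is_valid

    def test_every_variable_has_descriptions(self, hsn, ten):
        for net in (hsn, ten):
            assert all(v.description for v in net.variables.values())


class TestPrintedCpts:
    @pytest.mark.parametrize(
        "given, expected",
        [
            (("Good", "III–IV", "no"), (0.90, 0.10, 0.00)),
            (("Intermediate", "III–IV", "no"), (0.95, 0.05, 0.00)),
            (("Poor", "III–IV", "no"), (1.00, 0.00, 0.00)),
            (("Good", "I–II", "no"), (0.00, 0.80, 0.20)),
            (("Intermediate", "I–II", "no"), (0.05, 0.90, 0.05)),
            (("Poor", "I–II", "no"), (0.10, 0.90, 0.00)),
            (("Good", "0", "no"), (0.00, 0.00, 1.00)),
            (("Intermediate", "0", "no"), (0.00, 0.40, 0.60)),
            (("Poor", "0", "no"), (0.05, 0.95, 0.00)),
            (("Poor", "0", "yes"), (1.00, 0.00, 0.00)),
        ],
    )
    def test_hsn_cll_stage_rows(self, hsn, given, expected):
        assert hsn.transition.cpts["CLL stage"].row(*given) == expected

    @pytest.mark.parametrize(
        "given, expected",
        [
            (("None", "yes"), (0.01, 0.95, 0.04, 0.00)),
            (("AA", "yes"), (0.60, 0.21, 0.19, 0.00)),
            (("PA", "yes"), (0.75, 0.10, 0.15, 0.00)),
            (("MA", "yes"), (0.72, 0.25, 0.03, 0.00)),
            (("None", "no"), (0.00, 0.00, 0.00, 1.00)),
            (("PA", "no"), (0.00, 0.00, 0.00, 1.00)),
        ],
    )
    def test_ten_treatment_result_rows(self, ten, given, expected):
        assert ten.transition.cpts["Treatment result"].row(*given) == expected

    def test_death_from_other_cancers_worked_elicitation(self, hsn):
        cpt = hsn.transition.cpts["Death from other cancers"]
        assert cpt.row("yes", "no") == (0.007, 0.993)
        assert cpt.row("no", "no") == (0.0, 1.0)
        assert cpt.row("yes", "yes") == (1.0, 0.0)
        assert cpt.provenance == "paper"

    def test_printed_rows_survive_serialization_at_two_decimals(self, ten):
        reread = load_network("ten")
        for given, row in ten.transition.cpts["Treatment result"].table.items():
            got = reread.transition.cpts["Treatment result"].row(*given)
            assert tuple(round(x, 2) for x in got) == tuple(round(x, 2) for x in row)


class TestDocuments:
    def test_serialize_load_is_byte_identical(self):
        for name in NETWORK_NAMES:
            text = network_path(name).read_text(encoding="utf-8")
            assert dumps(load_network(name)) == text

    def test_unknown_network_rejected(self):
        with pytest.raises(KeyError):
            load_network("nonexistent")


class TestCoverage:
    def test_hsn_provenance_split(self, hsn):
        report = cpt_coverage_report(hsn)
        nodes = report["nodes"]
        assert nodes["CLL stage"]["transition"]["provenance"] == "paper"
        assert nodes["Death from other cancers"]["transition"]["provenance"] == "paper"
        assert report["counts"]["placeholder"] >= 1
        assert report["counts"]["paper"] + report["counts"]["placeholder"] == report["counts"]["total"]

    def test_ten_provenance_split(self):
        report = cpt_coverage_report("ten")
        assert report["nodes"]["Treatment result"]["transition"]["provenance"] == "paper"
        assert report["nodes"]["Health"]["transition"]["structure"] == "paper"
        assert report["counts"]["placeholder"] >= 1

    def test_fully_paper_sourced_toy_has_zero_placeholders(self):
        from conftest import make_chain_net

        net = make_chain_net()
        for model in (net.prior, net.transition):
            for cpt in model.cpts.values():
                cpt.provenance = "paper"
        report = cpt_coverage_report(net)
        assert report["counts"]["placeholder"] == 0


class TestScenarioPresets:
    def test_all_patients_is_empty(self, ten):
        preset = scenario_preset("all_patients", ten)
        assert not preset.evidence and not preset.interventions

    def test_group2_zeroes_fatal_toxicity_everywhere(self, ten):
        preset = scenario_preset("no_fatal_treatment_toxicity", ten)
        (iv,) = preset.interventions.entries
        assert iv.var == "Death from treatment" and iv.slices == "all"
        yes = ten.variable(iv.var).state_index("yes")
        for cpt in (iv.cpt, iv.prior_cpt):
            for row in cpt.table.values():
                assert row[yes] == 0.0 and sum(row) == pytest.approx(1.0)

    def test_group3_forces_complications_everywhere(self, ten):
        preset = scenario_preset("with_complications", ten)
        (iv,) = preset.interventions.entries
        assert iv.var == "Complications" and iv.slices == "all"
        yes = ten.variable(iv.var).state_index("yes")
        for cpt in (iv.cpt, iv.prior_cpt):
            for row in cpt.table.values():
                assert row[yes] == 1.0

    def test_preset_payload_validates_in_inference(self, ten):
        preset = scenario_preset("with_complications", ten)
        m = predict_marginals(ten, 1, "Complications", interventions=preset.interventions)
        np.testing.assert_allclose(m["Complications"].series("yes"), 1.0, atol=1e-12)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            scenario_preset("imaginary_group")

    def test_shipped_scenario_documents_parse(self, ten):
        from clldbn.networks import network_path
        from clldbn.scenario import read_scenario

        base = network_path("ten").parent / "scenarios"
        for name in ("no_fatal_treatment_toxicity", "with_complications"):
            ev, iv = read_scenario(base / f"{name}.yaml")
            m = predict_marginals(ten, 1, "Survival", ev, iv)
            np.testing.assert_allclose(m["Survival"].probabilities.sum(axis=1), 1.0)
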