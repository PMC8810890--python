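"""Exact inference: elimination engine, evidence, interventions, survival curves."""

import numpy as np
import pytest

import clldbn.inference as inf
from clldbn.inference import (
    EvidenceSet,
    InconsistentEvidenceError,
    Intervention,
    InterventionSet,
    IntractableError,
    brute_force_marginals,
    force_state_cpt,
    predict_marginals,
    survival_curve,
    zero_state_cpt,
)
from clldbn.networks._build import NetworkBuilder

from conftest import (
    make_chain_net,
    make_deterministic_net,
    make_geometric_death_net,
    make_random_net,
    make_single_var_net,
)


def make_chain3_net():
    """Intra-slice chain A -> B -> C with identity persistence on A."""
    b = NetworkBuilder("chain3")
    for nm in "ABC":
        b.variable(nm, ("yes", "no"))
    b.prior_cpt("A", [], {(): (0.3, 0.7)})
    b.prior_cpt("B", [("A", 0)], {("yes",): (0.8, 0.2), ("no",): (0.1, 0.9)})
    b.prior_cpt("C", [("B", 0)], {("yes",): (0.9, 0.1), ("no",): (0.4, 0.6)})
    b.transition_cpt("A", [("A", -1)], {("yes",): (1.0, 0.0), ("no",): (0.0, 1.0)})
    b.transition_cpt("B", [("A", 0)], {("yes",): (0.8, 0.2), ("no",): (0.1, 0.9)})
    b.transition_cpt("C", [("B", 0)], {("yes",): (0.9, 0.1), ("no",): (0.4, 0.6)})
    return b.build()


class TestBruteForce:
    def test_single_variable_prior(self):
        net = make_single_var_net(p_yes=0.3)
        m = brute_force_marginals(net, 0, "X")["X"]
        assert m.series("yes")[0] == pytest.approx(0.3, abs=1e-12)

    def test_independent_variables_product_form(self):
        b = NetworkBuilder("ind")
        b.variable("U", ("yes", "no"))
        b.variable("V", ("yes", "no"))
        b.prior_cpt("U", [], {(): (0.3, 0.7)})
        b.prior_cpt("V", [], {(): (0.6, 0.4)})
        b.transition_cpt("U", [("U", -1)], {("yes",): (1, 0), ("no",): (0, 1)})
        b.transition_cpt("V", [("V", -1)], {("yes",): (1, 0), ("no",): (0, 1)})
        net = b.build()
        m = brute_force_marginals(net, 1, ["U", "V"])
        assert m["U"].series("yes")[1] == pytest.approx(0.3)
        assert m["V"].series("yes")[1] == pytest.approx(0.6)

    def test_chain_bayes_inversion_by_hand(self):
        """Posterior on the chain root given leaf evidence, vs literal sums."""
        net = make_chain3_net()
        ev = EvidenceSet().add("C", 2, "yes")
        m = brute_force_marginals(net, 2, "A", ev)["A"]
        # hand enumeration: P(C=yes | A) = sum_b P(b | A) P(C=yes | b); A persists
        p_c_given_a = {
            "yes": 0.8 * 0.9 + 0.2 * 0.4,
            "no": 0.1 * 0.9 + 0.9 * 0.4,
        }
        num_yes = 0.3 * p_c_given_a["yes"]
        num_no = 0.7 * p_c_given_a["no"]
        assert m.series("yes")[2] == pytest.approx(num_yes / (num_yes + num_no), abs=1e-12)

    def test_state_space_cap(self):
        net = make_chain_net()
        with pytest.raises(IntractableError):
            brute_force_marginals(net, 3, "A", max_size=4)


class TestPredictMarginals:
    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_on_random_nets(self, trial):
        rng = np.random.default_rng(1000 + trial)
        net = make_random_net(rng)
        T = int(rng.integers(0, 3))
        ev = EvidenceSet()
        if rng.random() < 0.5:
            ev.add("V0", int(rng.integers(0, T + 1)), net.variable("V0").states[-1])
        query = [n for n in net.variables][:2]
        try:
            exact = predict_marginals(net, T, query, ev)
            oracle = brute_force_marginals(net, T, query, ev)
        except InconsistentEvidenceError:
            return
        for v in query:
            np.testing.assert_allclose(
                exact[v].probabilities, oracle[v].probabilities, atol=1e-9
            )

    def test_evidence_consistency_on_observed_variable(self, ten):
        ev = EvidenceSet().add("Treatment", 1, "PA")
        m = predict_marginals(ten, 2, "Treatment", ev)["Treatment"]
        assert m.series("PA")[1] == pytest.approx(1.0, abs=1e-12)

    def test_marginals_are_distributions(self, hsn):
        m = predict_marginals(hsn, 3, ["CLL stage", "Survival"])
        for traj in m.values():
            np.testing.assert_allclose(traj.probabilities.sum(axis=1), 1.0, atol=1e-9)

    def test_inconsistent_evidence_raises(self):
        net = make_deterministic_net()
        ev = EvidenceSet().add("A", 0, "a0")  # prior forces a1
        with pytest.raises(InconsistentEvidenceError):
            predict_marginals(net, 1, "B", ev)

    def test_factor_cap_raises_intractable(self, ten, monkeypatch):
        monkeypatch.setattr(inf, "MAX_FACTOR_SIZE", 8)
        with pytest.raises(IntractableError):
            predict_marginals(ten, 2, "Survival")

    def test_evidence_beyond_horizon_rejected(self):
        net = make_chain_net()
        with pytest.raises(ValueError, match="beyond horizon"):
            predict_marginals(net, 1, "A", EvidenceSet().add("A", 2, "yes"))


class TestInterventions:
    def test_cpt_surgery_changes_transition_behaviour(self):
        net = make_single_var_net(p_yes=0.5, p_stay_yes=0.5)
        frozen = force_state_cpt(net.transition.cpts["X"], 0)  # always yes
        iv = InterventionSet([Intervention("X", "all", cpt=frozen)])
        m = predict_marginals(net, 3, "X", interventions=iv)["X"]
        np.testing.assert_allclose(m.series("yes")[1:], 1.0, atol=1e-12)
        assert m.series("yes")[0] == pytest.approx(0.5)  # prior untouched

    def test_locality_earlier_slices_unchanged(self):
        net = make_chain_net()
        frozen = force_state_cpt(net.transition.cpts["B"], 0)
        iv = InterventionSet([Intervention("B", [2], cpt=frozen)])
        base = predict_marginals(net, 2, ["A", "B"])
        modified = predict_marginals(net, 2, ["A", "B"], interventions=iv)
        for v in ("A", "B"):
            np.testing.assert_allclose(
                base[v].probabilities[:2], modified[v].probabilities[:2], atol=1e-12
            )
        assert modified["B"].series("yes")[2] == pytest.approx(1.0)

    def test_replacement_must_match_parent_set(self, ten):
        foreign = ten.transition.cpts["Complications"]
        iv = InterventionSet(
            [Intervention("Death from treatment", "all", cpt=foreign)]
        )
        with pytest.raises(ValueError):
            predict_marginals(ten, 1, "Survival", interventions=iv)

    def test_zero_state_cpt_renormalizes(self, ten):
        cpt = zero_state_cpt(ten.transition.cpts["Death from treatment"], 0)
        for row in cpt.table.values():
            assert row[0] == 0.0
            assert sum(row) == pytest.approx(1.0, abs=1e-12)


class TestSurvivalCurve:
    def test_geometric_decay_closed_form(self):
        net = make_geometric_death_net(hazard=0.1)
        curve = survival_curve(net, 6)
        np.testing.assert_allclose(curve.survival, 0.9 ** np.arange(7), atol=1e-12)
        np.testing.assert_allclose(curve.months, 6.0 * np.arange(7))

    def test_absorbing_alive_intervention_freezes_curve(self):
        net = make_geometric_death_net(hazard=0.2)
        no_death = force_state_cpt(net.transition.cpts["Survival"], 0)
        iv = InterventionSet([Intervention("Survival", "all", cpt=no_death)])
        curve = survival_curve(net, 5, interventions=iv)
        np.testing.assert_allclose(curve.survival, curve.survival[0], atol=1e-12)

    def test_missing_survival_variable(self):
        with pytest.raises(KeyError, match="survival variable"):
            survival_curve(make_chain_net(), 3)
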