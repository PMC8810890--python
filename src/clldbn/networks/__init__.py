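"""Shipped CLL network definitions and scenario presets.

Two networks are distributed as YAML documents in the dbn_core schema:

- ``hsn`` — Health Status Network, 16 nodes per slice;
- ``ten`` — Treatment Effect Network, 18 nodes per slice.

Both use a 6-month slice.  The printed expert CPTs (the *CLL stage*
transition in the HSN, the *Treatment result* transition in the TEN, and
the worked *Death from other cancers* elicitation) are encoded exactly;
every other CPT is a clearly flagged placeholder so the engine runs
end-to-end without presenting invented numbers as published ones —
:func:`cpt_coverage_report` makes the split machine-readable.

Scenario presets reproduce the three published patient groups for the TEN:
all patients, patients with no fatal treatment toxicity (the death-from-
treatment CPT zeroed at every slice) and patients with complications (the
complications CPT forced to "yes" at every slice).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ..core import DynamicBayesianNetwork, validate_network
from ..inference import (
    EvidenceSet,
    Intervention,
    InterventionSet,
    force_state_cpt,
    zero_state_cpt,
)
from ..netdoc import loads
from ._hsn import build_hsn
from ._ten import build_ten

__all__ = [
    "NETWORK_NAMES",
    "SCENARIO_NAMES",
    "ScenarioPreset",
    "load_network",
    "network_path",
    "cpt_coverage_report",
    "scenario_preset",
]

NETWORK_NAMES = ("hsn", "ten")
SCENARIO_NAMES = ("all_patients", "no_fatal_treatment_toxicity", "with_complications")

_BUILDERS = {"hsn": build_hsn, "ten": build_ten}


def network_path(name: str) -> Path:
    """Filesystem path of a shipped network document."""
    if name not in NETWORK_NAMES:
        raise KeyError(f"unknown network {name!r}; available: {NETWORK_NAMES}")
    return Path(str(resources.files(__package__) / "data" / f"{name}.yaml"))


def load_network(name: str) -> DynamicBayesianNetwork:
    """Load and validate a shipped network ('hsn' or 'ten')."""
    path = network_path(name)
    dbn = loads(path.read_text(encoding="utf-8"))
    report = validate_network(dbn)
    assert report.is_valid, f"shipped document {name} failed validation:\n{report}"
    return dbn


def cpt_coverage_report(network: DynamicBayesianNetwork | str) -> dict:
    """Per-node provenance of numbers and structure, plus summary counts."""
    dbn = load_network(network) if isinstance(network, str) else network
    nodes = {}
    for name in dbn.variables:
        nodes[name] = {
            "prior": {
                "provenance": dbn.prior.cpts[name].provenance,
                "structure": dbn.prior.cpts[name].structure,
            },
            "transition": {
                "provenance": dbn.transition.cpts[name].provenance,
                "structure": dbn.transition.cpts[name].structure,
            },
        }
    all_cpts = [v[k]["provenance"] for v in nodes.values() for k in ("prior", "transition")]
    return {
        "network": dbn.name,
        "n_variables": dbn.n_variables,
        "nodes": nodes,
        "counts": {
            "paper": sum(p == "paper" for p in all_cpts),
            "placeholder": sum(p == "placeholder" for p in all_cpts),
            "total": len(all_cpts),
        },
    }


@dataclass
class ScenarioPreset:
    """A named evidence + intervention payload targeting a shipped network."""

    name: str
    network: str
    description: str
    evidence: EvidenceSet = field(default_factory=EvidenceSet)
    interventions: InterventionSet = field(default_factory=InterventionSet)


def scenario_preset(name: str, dbn: DynamicBayesianNetwork | None = None) -> ScenarioPreset:
    """The three patient-group presets for the Treatment Effect Network.

    - ``all_patients`` — empty payload (the average patient);
    - ``no_fatal_treatment_toxicity`` — every row of the *Death from
      treatment* CPT assigns probability 0 to "yes", at all slices;
    - ``with_complications`` — the *Complications* CPT puts all mass on
      "yes", at all slices.
    """
    if name not in SCENARIO_NAMES:
        raise KeyError(f"unknown scenario {name!r}; available: {SCENARIO_NAMES}")
    dbn = dbn if dbn is not None else load_network("ten")
    if name == "all_patients":
        return ScenarioPreset(name, dbn.name, "average patient; no a priori knowledge")
    if name == "no_fatal_treatment_toxicity":
        var = "Death from treatment"
        yes = dbn.variable(var).state_index("yes")
        iv = Intervention(
            var=var,
            slices="all",
            cpt=zero_state_cpt(dbn.transition.cpts[var], yes),
            prior_cpt=zero_state_cpt(dbn.prior.cpts[var], yes),
        )
        return ScenarioPreset(
            name,
            dbn.name,
            "patients with no treatment-related side effects leading to death",
            interventions=InterventionSet([iv]),
        )
    var = "Complications"
    yes = dbn.variable(var).state_index("yes")
    iv = Intervention(
        var=var,
        slices="all",
        cpt=force_state_cpt(dbn.transition.cpts[var], yes),
        prior_cpt=force_state_cpt(dbn.prior.cpts[var], yes),
    )
    return ScenarioPreset(
        name,
        dbn.name,
        "patients with complications (infections, autoimmune complications, "
        "other cancers or Richter syndrome) throughout follow-up",
        interventions=InterventionSet([iv]),
    )
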