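"""Evidence / intervention documents (YAML).

Format::

    evidence:
      - {var: Treatment, slice: 0, state: PA}
    interventions:
      - var: Death from treatment
        slices: all            # or an explicit list of slice indices
        cpt: {child: ..., parents: [...], rows: [...]}       # for slices >= 1
        prior_cpt: {child: ..., parents: [...], rows: [...]} # for slice 0

Replacement CPTs use the same sub-schema as network documents.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .inference import Evidence, EvidenceSet, Intervention, InterventionSet
from .netdoc import FormatError, cpt_from_dict, cpt_to_dict


def scenario_from_dict(doc: dict) -> tuple[EvidenceSet, InterventionSet]:
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise FormatError("scenario document must be a mapping")
    evidence = EvidenceSet(
        [
            Evidence(str(e["var"]), int(e["slice"]), str(e["state"]))
            for e in doc.get("evidence") or []
        ]
    )
    interventions = InterventionSet()
    for idoc in doc.get("interventions") or []:
        slices = idoc.get("slices", "all")
        if slices != "all":
            slices = [int(s) for s in slices]
        interventions.add(
            Intervention(
                var=str(idoc["var"]),
                slices=slices,
                cpt=cpt_from_dict(idoc["cpt"], "intervention") if "cpt" in idoc else None,
                prior_cpt=cpt_from_dict(idoc["prior_cpt"], "intervention")
                if "prior_cpt" in idoc
                else None,
            )
        )
    return evidence, interventions


def scenario_to_dict(evidence: EvidenceSet, interventions: InterventionSet) -> dict:
    doc: dict = {}
    if evidence:
        doc["evidence"] = [
            {"var": var, "slice": t, "state": state} for (var, t), state in evidence.items()
        ]
    if interventions:
        doc["interventions"] = []
        for iv in interventions.entries:
            idoc: dict = {"var": iv.var, "slices": iv.slices}
            if iv.cpt is not None:
                idoc["cpt"] = cpt_to_dict(iv.cpt)
            if iv.prior_cpt is not None:
                idoc["prior_cpt"] = cpt_to_dict(iv.prior_cpt)
            doc["interventions"].append(idoc)
    return doc


def read_scenario(path: str | Path) -> tuple[EvidenceSet, InterventionSet]:
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise FormatError(f"unparseable scenario document: {exc}") from exc
    return scenario_from_dict(doc)


def write_scenario(
    evidence: EvidenceSet, interventions: InterventionSet, path: str | Path
) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            scenario_to_dict(evidence, interventions),
            sort_keys=False,
            allow_unicode=True,
            default_flow_style=None,
            width=100,
        ),
        encoding="utf-8",
    )
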