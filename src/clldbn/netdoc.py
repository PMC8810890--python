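"""Network-definition documents.

Schema (version 1), YAML or JSON::

    schema_version: 1
    name: hsn
    slice_duration_months: 6
    survival_variable: Survival
    variables:
      - name: Age
        description: "..."
        states: ["<= 65 years", "> 65 years"]
    prior:
      cpts:
        - child: Age
          parents: []
          provenance: placeholder     # paper | placeholder
          structure: inferred         # paper | inferred
          rows:
            - given: []
              p: [0.35, 0.65]
    transition:
      cpts:
        - child: Age
          parents: [{var: Age, offset: -1}]
          ...

Writing is canonical (stable key order, block style, full float precision),
so write(read(doc)) is byte-identical for documents produced by this module.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .core import (
    ConditionalProbabilityTable,
    DynamicBayesianNetwork,
    PriorSliceModel,
    SlicedRef,
    TransitionModel,
    Variable,
)

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """The document does not parse against the network schema."""


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise FormatError(f"{where}: missing required key {key!r}")
    return mapping[key]


def cpt_from_dict(doc: dict, where: str = "cpt") -> ConditionalProbabilityTable:
    child = _require(doc, "child", where)
    raw_parents = _require(doc, "parents", where)
    try:
        parents = tuple(SlicedRef(p["var"], int(p.get("offset", 0))) for p in raw_parents)
    except (TypeError, KeyError, ValueError) as exc:
        raise FormatError(f"{where}/{child}: bad parent list ({exc})") from exc
    rows = _require(doc, "rows", where)
    table: dict[tuple[str, ...], tuple[float, ...]] = {}
    for row in rows:
        given = tuple(str(s) for s in row.get("given", ()))
        if given in table:
            raise FormatError(f"{where}/{child}: duplicate row for {given!r}")
        try:
            table[given] = tuple(float(x) for x in row["p"])
        except (TypeError, KeyError, ValueError) as exc:
            raise FormatError(f"{where}/{child}: bad probability row ({exc})") from exc
    return ConditionalProbabilityTable(
        child=child,
        parents=parents,
        table=table,
        provenance=str(doc.get("provenance", "placeholder")),
        structure=str(doc.get("structure", "inferred")),
    )


def network_from_dict(doc: dict) -> DynamicBayesianNetwork:
    if not isinstance(doc, dict):
        raise FormatError("network document must be a mapping")
    version = int(_require(doc, "schema_version", "document"))
    if version != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema_version {version}")
    variables: dict[str, Variable] = {}
    for vdoc in _require(doc, "variables", "document"):
        name = _require(vdoc, "name", "variables")
        if name in variables:
            raise FormatError(f"duplicate variable name {name!r}")
        variables[name] = Variable(
            name=name,
            states=tuple(str(s) for s in _require(vdoc, "states", f"variables/{name}")),
            description=str(vdoc.get("description", "")),
        )
    prior = PriorSliceModel()
    for cdoc in _require(_require(doc, "prior", "document"), "cpts", "prior"):
        cpt = cpt_from_dict(cdoc, "prior")
        prior.cpts[cpt.child] = cpt
    transition = TransitionModel()
    for cdoc in _require(_require(doc, "transition", "document"), "cpts", "transition"):
        cpt = cpt_from_dict(cdoc, "transition")
        transition.cpts[cpt.child] = cpt
    return DynamicBayesianNetwork(
        name=str(_require(doc, "name", "document")),
        variables=variables,
        prior=prior,
        transition=transition,
        slice_duration_months=float(doc.get("slice_duration_months", 6)),
        survival_variable=doc.get("survival_variable"),
        schema_version=version,
    )


def _float_repr(x: float):
    # keep integral probabilities as 0.0/1.0 etc.; full precision otherwise
    return float(x)


def cpt_to_dict(cpt: ConditionalProbabilityTable) -> dict:
    return {
        "child": cpt.child,
        "parents": [{"var": p.var, "offset": p.offset} for p in cpt.parents],
        "provenance": cpt.provenance,
        "structure": cpt.structure,
        "rows": [
            {"given": list(given), "p": [_float_repr(x) for x in row]}
            for given, row in cpt.table.items()
        ],
    }


def network_to_dict(dbn: DynamicBayesianNetwork) -> dict:
    cpt_doc = cpt_to_dict
    doc: dict = {
        "schema_version": dbn.schema_version,
        "name": dbn.name,
        "slice_duration_months": _float_repr(dbn.slice_duration_months),
    }
    if dbn.survival_variable is not None:
        doc["survival_variable"] = dbn.survival_variable
    doc["variables"] = [
        {"name": v.name, "description": v.description, "states": list(v.states)}
        for v in dbn.variables.values()
    ]
    doc["prior"] = {"cpts": [cpt_doc(dbn.prior.cpts[n]) for n in dbn.variables if n in dbn.prior.cpts]}
    doc["transition"] = {
        "cpts": [cpt_doc(dbn.transition.cpts[n]) for n in dbn.variables if n in dbn.transition.cpts]
    }
    return doc


def dumps(dbn: DynamicBayesianNetwork) -> str:
    """Canonical YAML serialization (stable order, unicode intact)."""
    return yaml.safe_dump(
        network_to_dict(dbn),
        sort_keys=False,
        allow_unicode=True,
        default_flow_style=None,
        width=100,
    )


def loads(text: str) -> DynamicBayesianNetwork:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise FormatError(f"unparseable document: {exc}") from exc
    return network_from_dict(doc)


def read_network(path: str | Path) -> DynamicBayesianNetwork:
    """Read a network document (YAML, or JSON which YAML subsumes)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return network_from_dict(json.loads(path.read_text(encoding="utf-8")))
    return loads(path.read_text(encoding="utf-8"))


def write_network(dbn: DynamicBayesianNetwork, path: str | Path) -> None:
    Path(path).write_text(dumps(dbn), encoding="utf-8")
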