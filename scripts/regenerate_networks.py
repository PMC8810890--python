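"""Regenerate the shipped network and scenario documents from the builders.

Run from the repository root after editing the builder modules:

    python scripts/regenerate_networks.py

Tests assert that the shipped YAML round-trips byte-identically through the
canonical serializer, so builders and documents cannot drift silently.
"""

from __future__ import annotations

from pathlib import Path

from clldbn import netdoc, validate_network
from clldbn.networks import _hsn, _ten, scenario_preset
from clldbn.scenario import write_scenario

DATA = Path(__file__).resolve().parent.parent / "src" / "clldbn" / "networks" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    (DATA / "scenarios").mkdir(exist_ok=True)
    for name, build in (("hsn", _hsn.build_hsn), ("ten", _ten.build_ten)):
        dbn = build()
        report = validate_network(dbn)
        if not report.is_valid:
            raise SystemExit(f"{name} failed validation:\n{report}")
        netdoc.write_network(dbn, DATA / f"{name}.yaml")
        print(f"wrote {DATA / f'{name}.yaml'} ({dbn.n_variables} variables)")
    ten = netdoc.read_network(DATA / "ten.yaml")
    for scen in ("all_patients", "no_fatal_treatment_toxicity", "with_complications"):
        preset = scenario_preset(scen, ten)
        write_scenario(preset.evidence, preset.interventions, DATA / "scenarios" / f"{scen}.yaml")
        print(f"wrote scenario {scen}")


if __name__ == "__main__":
    main()
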