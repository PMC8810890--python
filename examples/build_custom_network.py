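"""Author, validate and serialize a small custom two-slice network.

A two-node disease/death toy: death risk depends on disease activity, death
is absorbing.  The same schema ships the full CLL networks, so anything
built this way plugs into inference, sampling and the CLI.
"""

import numpy as np

from clldbn import netdoc, survival_curve, validate_network
from clldbn.networks._build import NetworkBuilder, bern, det

b = NetworkBuilder("toy_disease", survival_variable="Survival")
b.variable("Active disease", ("yes", "no"), "disease currently active")
b.variable("Survival", ("yes", "no"), "patient alive")
b.prior_cpt("Active disease", [], {(): bern(0.4)})
b.prior_cpt("Survival", [], {(): det(("yes", "no"), "yes")})
b.transition_cpt("Active disease", [("Active disease", -1)],
                 {("yes",): bern(0.8), ("no",): bern(0.1)})
b.transition_cpt(
    "Survival",
    [("Survival", -1), ("Active disease", -1)],
    {
        ("yes", "yes"): bern(0.90),   # 10%/slice hazard while active
        ("yes", "no"): bern(0.99),
        ("no", "yes"): det(("yes", "no"), "no"),  # death absorbing
        ("no", "no"): det(("yes", "no"), "no"),
    },
)
net = b.build()

report = validate_network(net)
print("validation:", report)

curve = survival_curve(net, 10)
print("P(alive) per slice:", np.round(curve.survival, 3).tolist())

text = netdoc.dumps(net)
print(f"serialized document: {len(text)} bytes; round-trip stable:",
      netdoc.dumps(netdoc.loads(text)) == text)
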