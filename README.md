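# clldbn

Discrete two-slice dynamic Bayesian networks (DBNs) for predicting health
status and treatment effect in chronic lymphocytic leukemia (CLL).

CLL is the most common adult leukemia, with a course that varies from
indolent to rapidly fatal, and there is too little patient-level data to
*learn* a prognostic model — but a rich literature and expert practice to
*encode* one. This package is built for that setting: it provides a
generic engine for discrete dynamic Bayesian networks whose conditional
probability tables (CPTs) are elicited from literature risks and expert
judgment, plus two shipped CLL networks — the 16-node **Health Status
Network (HSN)** and the 18-node **Treatment Effect Network (TEN)** — on a
6-month time grid. It is aimed at biostatisticians and modellers who want
to encode, audit and interrogate belief networks of this kind: predict
survival trajectories, inject patient-specific knowledge, and check every
number's provenance.

## The model

A DBN here is a pair (B₀, B→): a Bayesian network B₀ over the variables
X^(0) at diagnosis, and a transition network B→ giving each variable's
distribution at slice t conditioned on parents in slices t−1 and t
(first-order Markov). The joint over a horizon 0..T factorises as

    P(X^(0:T)) = ∏ᵢ P(Xᵢ^(0) | π(Xᵢ; B₀)) · ∏ₜ ∏ᵢ P(Xᵢ^(t) | π(Xᵢ; B→))

Everything else follows from this factorisation:

- **Exact inference** — per-slice posterior marginals P(Xᵢ^(t) | evidence)
  by variable elimination (min-fill ordering) over the unrolled network,
  with typed errors for inconsistent evidence and intractable queries.
- **Interventions** — "a priori knowledge" is injected by replacing CPTs
  at chosen slices before inference, composable with hard evidence; this
  is how patient subgroups and treatment scenarios are expressed.
- **Elicitation calculus** — literature risks stated over long horizons
  are converted to per-slice probabilities via P_k = −(k/m)·ln(1−P_m)
  (with an exact constant-hazard variant 1−(1−P_m)^{k/m}), and expert
  "r× more often" statements are applied on the odds scale.
- **Forward sampling** — seeded, prefix-stable ancestral sampling of
  synthetic cohorts, used as an independent Monte-Carlo check on the
  exact engine.
- **Curve utilities** — survival-curve CSV I/O, the mean absolute yearly
  difference metric over the first 60 months, and sample-size-weighted
  pooling of trial curves with 95% bands.

The shipped networks encode the published expert tables exactly (the HSN
*CLL stage* transition, the TEN *Treatment result* transition, and the
worked *Death from other cancers* elicitation); all remaining CPTs are
clearly flagged placeholders so the networks run end-to-end without
passing invented numbers off as published ones — `cpt_coverage_report`
shows the split per node. See `docs/methods.md` for the full account.

## Worked example

```python
from clldbn import EvidenceSet, load_network, predict_marginals, survival_curve
from clldbn.networks import scenario_preset

ten = load_network("ten")          # 18 variables per 6-month slice

# reading a published expert row back through the inference engine:
ev = EvidenceSet().add("Treatment", 0, "PA").add("Survival", 0, "yes")
m = predict_marginals(ten, 1, "Treatment result", ev)["Treatment result"]
print({s: round(float(p), 2) for s, p in m.at(1).items()})

# ten-year survival for three patient groups (CPT interventions):
for name in ("all_patients", "no_fatal_treatment_toxicity", "with_complications"):
    preset = scenario_preset(name, ten)
    c = survival_curve(ten, 20, preset.evidence, preset.interventions)
    print(f"{name:30s} P(alive) at 10y = {c.survival[20]:.3f}")
```

prints

```
{'CR+PR': 0.75, 'SD': 0.1, 'PD': 0.15, 'Death': 0.0}
all_patients                   P(alive) at 10y = 0.626
no_fatal_treatment_toxicity    P(alive) at 10y = 0.703
with_complications             P(alive) at 10y = 0.468
```

The first line is the expert CPT row for purine analogs in a living
patient, recovered exactly by conditioning on the node's full parent set.
The survival values show the scenario machinery at work: removing fatal
treatment toxicity raises 10-year survival, forcing complications lowers
it, and the ordering holds pointwise at every slice. Because most CPTs
are placeholders, the *absolute* levels are illustrative; the ordering is
the robust prediction.

The `examples/` directory has one short script per capability
(elicitation, expert-table queries, scenarios, Monte-Carlo checking,
authoring custom networks). A thin CLI covers the same ground from a
shell:

```
cll-dbn validate --network hsn
cll-dbn survival --network ten --slices 20 --scenario with_complications --out curve.csv
cll-dbn rescale --p 0.3 --m 50 --k 1           # -> 0.007133
cll-dbn compare --predicted curve.csv --reference registry.csv
```

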