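interventions:
- var: Complications
  slices: all
  cpt:
    child: Complications
    parents:
    - {var: Complications, offset: -1}
    - {var: Treatment, offset: -1}
    provenance: intervention
    structure: inferred
    rows:
    - given: ['yes', None]
      p: [1.0, 0.0]
    - given: ['yes', AA]
      p: [1.0, 0.0]
    - given: ['yes', PA]
      p: [1.0, 0.0]
    - given: ['yes', MA]
      p: [1.0, 0.0]
    - given: ['no', None]
      p: [1.0, 0.0]
    - given: ['no', AA]
      p: [1.0, 0.0]
    - given: ['no', PA]
      p: [1.0, 0.0]
    - given: ['no', MA]
      p: [1.0, 0.0]
  prior_cpt:
    child: Complications
    parents: []
    provenance: intervention
    structure: inferred
    rows:
    - given: []
      p: [1.0, 0.0]
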