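interventions:
- var: Death from treatment
  slices: all
  cpt:
    child: Death from treatment
    parents:
    - {var: Treatment, offset: -1}
    - {var: Death from treatment, offset: -1}
    provenance: intervention
    structure: inferred
    rows:
    - given: [None, 'yes']
      p: [0.0, 1.0]
    - given: [None, 'no']
      p: [0.0, 1.0]
    - given: [AA, 'yes']
      p: [0.0, 1.0]
    - given: [AA, 'no']
      p: [0.0, 1.0]
    - given: [PA, 'yes']
      p: [0.0, 1.0]
    - given: [PA, 'no']
      p: [0.0, 1.0]
    - given: [MA, 'yes']
      p: [0.0, 1.0]
    - given: [MA, 'no']
      p: [0.0, 1.0]
  prior_cpt:
    child: Death from treatment
    parents: []
    provenance: intervention
    structure: inferred
    rows:
    - given: []
      p: [0.0, 1.0]
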