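name: metformin
physchem:
  mw: 129.16
  logp: -1.43
  pka:
  - kind: base
    value: 2.8
  - kind: acid
    value: 11.5
  hbd: 3
  hba: 1
  psa: 91.5
  fu_plasma: 1.0
maternal_pk:
  cl: 30.0
  vc: 100.0
  peripherals: []
  ka: 0.9
  f: 0.55
  tlag: 0.0
regimen: 500mg q12h x30 po
reference_clearances:
  clsec: 21.73
  clre: 138.37
effective:
  logd74: 2.9671
  logp: -1.4299
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; the tabulated LogP reproduces the published reuptake clearance.
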