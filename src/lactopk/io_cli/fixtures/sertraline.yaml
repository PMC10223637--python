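name: sertraline
physchem:
  mw: 306.0
  logp: 5.5
  pka:
  - kind: base
    value: 9.43
  hbd: 1
  hba: 1
  psa: 12.03
  fu_plasma: 0.023
maternal_pk:
  cl: 96.0
  vc: 1500.0
  peripherals: []
  ka: 0.5
  f: 0.44
  tlag: 0.0
regimen: 50mg q24h x30 po
reference_clearances:
  clsec: 8925.7
  clre: 3597.49
effective:
  logd74: 1.9898
  logp: 5.0
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; note the tabulated LogP does NOT reproduce the published reuptake clearance.
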