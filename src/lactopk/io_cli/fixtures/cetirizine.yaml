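name: cetirizine
physchem:
  mw: 388.9
  logp: 1.5
  pka:
  - kind: acid
    value: 2.9
  - kind: base
    value: 8.0
  - kind: base
    value: 2.2
  hbd: 1
  hba: 5
  psa: 53.0
  fu_plasma: 0.07
maternal_pk:
  cl: 3.3
  vc: 30.0
  peripherals: []
  ka: 1.5
  f: 1.0
  tlag: 0.0
regimen: 10mg q24h x30 po
reference_clearances:
  clsec: 3031.27
  clre: 1922.74
effective:
  logd74: 3.24
  logp: 3.48
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; note the tabulated LogP does NOT reproduce the published reuptake clearance.
therapeutic_infant_dose: 0.5
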