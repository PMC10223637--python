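name: valproic_acid
physchem:
  mw: 144.21
  logp: 2.75
  pka:
  - kind: acid
    value: 4.8
  hbd: 1
  hba: 2
  psa: 37.3
  fu_plasma: 0.14
maternal_pk:
  cl: 0.5
  vc: 11.0
  peripherals: []
  ka: 1.5
  f: 1.0
  tlag: 0.0
regimen: 2100mg q24h x30 po
reference_clearances:
  clsec: 248.39
  clre: 1423.15
effective:
  logd74: 2.4555
  logp: 2.75
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; the tabulated LogP reproduces the published reuptake clearance.
therapeutic_infant_dose: 40.0
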