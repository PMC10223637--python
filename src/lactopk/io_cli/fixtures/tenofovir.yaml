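name: tenofovir
physchem:
  mw: 287.21
  logp: 1.87
  pka:
  - kind: acid
    value: 1.35
  - kind: acid
    value: 6.7
  - kind: base
    value: 3.8
  hbd: 3
  hba: 8
  psa: 136.38
  fu_plasma: 0.993
maternal_pk:
  cl: 45.0
  vc: 300.0
  peripherals: []
  ka: 1.0
  f: 0.25
  tlag: 0.0
regimen: 300mg q24h x30 po
reference_clearances:
  clsec: 51.96
  clre: 129.0
effective:
  logd74: 3.6792
  logp: -1.6001
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; note the tabulated LogP does NOT reproduce the published reuptake clearance.
therapeutic_infant_dose: 6.5
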