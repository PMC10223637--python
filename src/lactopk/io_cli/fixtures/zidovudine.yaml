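name: zidovudine
physchem:
  mw: 267.24
  logp: 0.05
  pka:
  - kind: acid
    value: 9.7
  hbd: 2
  hba: 6
  psa: 108.3
  fu_plasma: 0.8
maternal_pk:
  cl: 100.0
  vc: 100.0
  peripherals: []
  ka: 2.0
  f: 0.64
  tlag: 0.0
regimen: 300mg q12h x30 po
reference_clearances:
  clsec: 431.04
  clre: 345.1
effective:
  logd74: 0.0022
  logp: 0.05
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; the tabulated LogP reproduces the published reuptake clearance.
therapeutic_infant_dose: 24.0
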