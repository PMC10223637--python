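name: caffeine
physchem:
  mw: 194.2
  logp: -0.07
  pka:
  - kind: base
    value: 0.8
  hbd: 0
  hba: 3
  psa: 58.44
  fu_plasma: 0.7
maternal_pk:
  cl: 6.0
  vc: 36.0
  peripherals: []
  ka: 3.0
  f: 1.0
  tlag: 0.0
regimen: 100mg q8h x30 po
reference_clearances:
  clsec: 824.02
  clre: 603.21
effective:
  logd74: -0.0
  logp: -0.07
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; the tabulated LogP reproduces the published reuptake clearance.
therapeutic_infant_dose: 5.0
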