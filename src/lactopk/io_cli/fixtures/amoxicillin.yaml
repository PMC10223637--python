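name: amoxicillin
physchem:
  mw: 365.4
  logp: 0.87
  pka:
  - kind: acid
    value: 3.23
  - kind: base
    value: 7.43
  hbd: 4
  hba: 7
  psa: 158.0
  fu_plasma: 0.85
maternal_pk:
  cl: 15.0
  vc: 15.0
  peripherals: []
  ka: 1.2
  f: 0.9
  tlag: 0.0
regimen: 1000mg q8h x30 po
reference_clearances:
  clsec: 46.9
  clre: 263.47
effective:
  logd74: 4.1199
  logp: 0.87
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; the tabulated LogP reproduces the published reuptake clearance.
therapeutic_infant_dose: 50.0
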