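name: nevirapine
physchem:
  mw: 266.3
  logp: 1.93
  pka:
  - kind: base
    value: 2.8
  hbd: 1
  hba: 4
  psa: 58.1
  fu_plasma: 0.4
maternal_pk:
  cl: 3.0
  vc: 75.0
  peripherals: []
  ka: 1.0
  f: 0.93
  tlag: 0.0
regimen: 200mg q12h x30 po
reference_clearances:
  clsec: 2413.86
  clre: 1015.01
effective:
  logd74: 0.0001
  logp: 1.93
provenance:
  physchem: published
  maternal_pk: user
  reference_clearances: published
  effective: backcalculated
notes: Physicochemical values are from the published property table; maternal PK parameters
  are literature-plausible placeholders (the source models are not redistributable).
  The 'effective' block holds the LogD7.4/LogP inputs back-calculated from the published
  clearances; the tabulated LogP reproduces the published reuptake clearance.
therapeutic_infant_dose: 12.0
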