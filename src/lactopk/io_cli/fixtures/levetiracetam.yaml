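name: levetiracetam
physchem:
  mw: 170.21
  logp: -0.6
  pka: []
  hbd: 1
  hba: 2
  psa: 63.4
  fu_plasma: 0.9
maternal_pk:
  cl: 3.6
  vc: 40.0
  peripherals: []
  ka: 2.0
  f: 1.0
  tlag: 0.0
regimen: 1500mg q12h x30 po
reference_clearances:
  clsec: 445.38
  clre: 357.77
effective:
  logd74: -0.0
  logp: -0.6
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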