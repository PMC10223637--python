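# lactopk

Bottom-up prediction of medicine concentrations in human milk, and of the
resulting infant dose, from a handful of physicochemical properties.

The workflow:

1. **physchem** — drug records (MW, LogP, pKa set, HBD, PSA, unbound plasma
   fraction) and Henderson–Hasselbalch LogD at arbitrary pH, with optional
   measured overrides.
2. **milk_transfer** — semi-mechanistic log-linear regressions for the
   bidirectional plasma↔milk clearances (secretion from PSA/MW/LogD7.4,
   reuptake from LogP/HBD), milk lipid partition and unbound milk fractions,
   and the closed-form steady-state milk-to-plasma (M/P) AUC ratio
   `fu_plasma·CLsec / (fu_milk_total·CLre)`.
3. **pk_engine** — a reduced 1–3 compartment maternal PK model (IV bolus,
   infusion, first-order oral absorption with lag) coupled to a fixed-volume
   0.5 L milk compartment; stiff-capable integration (`LSODA`/`BDF`) or exact
   matrix-exponential propagation, dose events handled by solver restarts,
   periodic steady-state driver, and basic NCA (terminal slope, AUC to
   infinity).
4. **metrics** — interval AUC/Cmax/Cave, M/P ratio, daily infant dosage
   (DID, 150 mL/kg/day milk intake), relative infant dose (RID, 60.3 kg
   maternal weight), RID vs therapeutic infant dose, and fold-error / GMFE
   evaluation statistics.
5. **population** — Monte-Carlo population simulation with log-normal
   inter-individual variability (default: milk volume, GSD 1.16) and
   5th/50th/95th percentile bands.
6. **io_cli** — YAML drug configs with provenance tags, ten packaged drug
   fixtures, a synthetic drug generator for property-based testing, report
   orchestration and the command-line interface.

Ten physicochemically diverse medicines ship as fixtures (amoxicillin,
caffeine, cetirizine, levetiracetam, metformin, nevirapine, sertraline,
tenofovir, valproic acid, zidovudine). Their physicochemical blocks carry
published values; their maternal PK parameters are literature-plausible
placeholders tagged `provenance: user` (the original whole-body models are
not redistributable), so simulated absolute concentrations are illustrative
while all clearance/binding/M-P derivations are faithful.

## CLI

```sh
lactopk fixtures list
lactopk fixtures show caffeine
lactopk derive --all-fixtures               # clearances, milk binding, M/P
lactopk derive --all-fixtures --effective   # with back-calculated inputs
lactopk simulate caffeine --regimen "100mg q8h x6 po" -o profile.csv
lactopk steady-state caffeine -o ss.csv
lactopk infant-dose caffeine                # full workflow + RID report
lactopk population caffeine --n 1000 --seed 1 -o bands.csv
```

Regimen grammar: `"<dose>mg q<tau>h [x<n>] <po|iv|ivinf[:<dur>h]>"`,
e.g. `"1000mg q8h x15 po"` or `"500mg q12h x10 ivinf:1h"`.

## Python API sketch

```python
from lactopk import build_model, simulate_to_steady_state, infant_dose_report
from lactopk.io_cli import load_fixture
from lactopk.milk_transfer import derive_milk_transfer

cfg = load_fixture("caffeine")
transfer = derive_milk_transfer(cfg.physchem)      # CLsec, CLre, fu, M/P
model = build_model(cfg.physchem, cfg.maternal_pk, transfer)
sim = simulate_to_steady_state(model, (100.0, 8.0, "oral"))
report = infant_dose_report(sim, daily_maternal_dose=300.0, therapeutic_dose=5.0)
print(report.mp_ratio, report.rid_ave)
```

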