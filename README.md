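# fosfopk

Population pharmacokinetics of intravenous fosfomycin in critically ill
patients with and without kidney replacement therapy (KRT): a tested,
reusable pipeline for model-based dose optimization.

Fosfomycin is a small, hydrophilic, renally cleared antibiotic with
negligible protein binding, which makes it highly dialyzable. Selecting an
effective dose for an intensive-care patient therefore depends on both the
patient's own kidney function and on the dialysis modality — continuous KRT
(CKRT, low dialysate flow, running for days) removes drug very differently
from prolonged-intermittent KRT (PIKRT, high flow, 6–8 h sessions). This
package implements a population pharmacokinetic model that separates those
two elimination routes and uses it to evaluate licensed dosing regimens
(12–24 g/day) by Monte Carlo simulation.

## The model

Two-compartment disposition with zero-order (infusion) input and two
parallel first-order clearances acting on the central compartment:

```
CL_body = θ_CL · (eGFR_MDRD / 48.4)^θ_KF · exp(η_CL)     [= 0 if anuric]
CL_KRT  = θ_DIAL · (Q_D / 42)^θ_QD                        [= 0 off dialysis]
V_P(t)  = θ_VP · (1 + TSFD · θ_T) · exp(η_VP)             [growth if anuric]
V_C     = θ_VC · exp(η_VC)
```

where eGFR_MDRD is the MDRD estimated glomerular filtration rate
(mL/min/1.73 m²), Q_D the dialysate flow (mL/min), TSFD the time since
first dose (min), and anuria means a 24-h urine output below 100 mL.
Inter-individual variability (η) is lognormal; residual error is combined
proportional + additive. At the default (published) estimates the typical
body clearance is 1.6 L/h at the reference eGFR of 48.4 and the typical
dialysis clearance is 2.0 L/h at Q_D = 42 mL/min.

Dose adequacy is judged by two pharmacokinetic/pharmacodynamic indices on
the 24–48 h window: AUC₂₄₋₄₈/MIC (bacteriostatic target 22.7, bactericidal
83.3) and %T₂₄₋₄₈>MIC (bactericidal target 69.0). The probability of
target attainment (PTA) is the fraction of 2,000 simulated subjects
attaining a target at a given MIC.

The package also contains a Laplace-approximation maximum marginal
likelihood estimator (a stand-in for FOCE-I) with likelihood-ratio testing,
stepwise covariate search, conditional weighted residuals and a
prediction-corrected visual predictive check — plus a synthetic-data
generator that emulates the four source studies' designs (no clinical data
are deposited for this analysis).

## Worked example

```python
import numpy as np
from fosfopk import typical_cl_body, typical_cl_krt
from fosfopk.scenarios import Scenario, run_scenario

print(typical_cl_body(48.4, anuric=False, study_b=False))  # 1.6  (L/h)
print(typical_cl_krt(42.0, krt_active=True))               # 2.0  (L/h)

sc = Scenario("4gTID", "ckrt", "anuria", n_subjects=2000, seed=5)
res = run_scenario(sc)
print(res["bactericidal_auc"].at_mic(32.0))   # 0.9205
print(res["bacteriostatic_auc"].at_mic(32.0)) # 1.0
```

The last two numbers say: for anuric patients on continuous KRT receiving
4 g three times daily, 92 % of simulated subjects reach the bactericidal
AUC₂₄₋₄₈/MIC target at an MIC of 32 mg/L (so 4 g TID is the lowest
bactericidal dosage at the 90 % level for this stratum), and all of them
reach the bacteriostatic target.

From the shell, the same machinery is exposed as subcommands:

```bash
fosfopk generate --seed 1 --out cohort.csv         # synthetic 45-subject cohort
fosfopk fit --dataset cohort.csv --out fit.txt     # mixed-effects estimation
fosfopk pta --seed 1 --out pta.tsv                 # full scenario grid
fosfopk recommend --pta-table pta.tsv --out rec.tsv
fosfopk vpc --dataset cohort.csv --seed 1 --out vpc.tsv
```

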