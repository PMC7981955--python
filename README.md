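# creapew

Solute mass balance, excretion kinetics and protein-energy-wasting (PEW)
phenotyping for hemodialysis cohorts.

Patients on maintenance hemodialysis lose small water-soluble solutes —
arginine, guanidinoacetate (GAA), creatine and creatinine — into the spent
dialysate at every session. Because the kidney performs the rate-limiting
step of creatine synthesis (arginine → GAA by AGAT), dialysis patients may
combine impaired synthesis with unopposed dialytic losses, a plausible
contributor to the PEW phenotype (low muscle mass, low protein intake,
hypoalbuminemia, low BMI) and to severe fatigue. This package implements
the complete quantitative pipeline for that question, for clinical
researchers analysing per-session cohort tables (pre/post plasma
concentrations, total spent-dialysate volume and concentration, and
interdialytic 24-h urine collections).

## What it computes

**Intradialytic plasma changes** — absolute decrease `pre − post` (μmol/L)
and proportional decrease `100·(pre − post)/pre` (%), summarised as the
mean of per-patient ratios.

**Compartmental mass balance** — per session,

- total loss (μmol) = `V_dialysate · D_X`
- extracellular loss = `P_pre · ECV_pre − P_post · ECV_post`
- intracellular loss = total − extracellular,

with ECV estimated anthropometrically: `ECV = √weight · height` (primary)
or `ECV = weight^0.6469 · height_cm^0.7236 · 0.02154` (sensitivity). A large
intracellular component indicates an intra- to extracellular shift during
the session.

**Daily excretion rates** — dialysate rate `V·D·n/7` (n sessions/week),
urinary rate as the mean of two 24-h collections (patients with residual
diuresis > 200 mL/24-h), and the urinary share of the combined rate.

**PEW phenotype** — skeletal muscle index from the combined creatinine
excretion rate (1 g creatinine/24-h = 8.84 mmol ≙ 22.73 kg muscle, divided
by height²); Maroni protein intake
`(6.25·(0.028·CUER + 0.031·BW) + UPE)/BW`; Daugirdas second-generation
`Kt/V = −ln(R − 0.008·t) + (4 − 3.5·R)·UF/W`; CIS fatigue-severity score;
and the five criterion flags (SMI < 10.76/6.76 kg/m² by sex, protein
< 0.8 g/kg/24-h, albumin < 38 g/L, BMI < 23 kg/m², fatigue ≥ 35).

**Associations** — logistic models of each PEW flag on each predialysis
plasma level, scaled per 1-SD decrease (per halving for the right-skewed
creatine), sex-adjusted and multivariable (age, sex, BSA, vintage,
hs-CRP), with the full sensitivity grid (95th-percentile exclusion, access
type, Kt/V, medications, residual diuresis, dialysate-loss predictors).

**Synthetic cohort generator** — a two-pool (intracellular/extracellular)
kinetic simulator with a partition coefficient for actively maintained
gradients, plus covariate and logistic-outcome sampling with recorded true
coefficients, so every estimator is testable against ground truth.

## Worked example

Running the numbered analysis scripts on the default synthetic cohort
(59 patients, seed 42):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_mass_balance.py
```

prints

```
mass balance for 59 patients (abraham ECV) -> results/
  arginine           plasma decrease  27.4 %   total loss       1907 μmol   EC  19 % / IC  81 %
  creatine           plasma decrease  13.7 %   total loss        803 μmol   EC   8 % / IC  92 %
  creatinine         plasma decrease  54.7 %   total loss      19259 μmol   EC  33 % / IC  67 %
  guanidinoacetate   plasma decrease  25.5 %   total loss         35 μmol   EC  21 % / IC  79 %
```

i.e. creatine shows the smallest plasma decrease yet ~90% of its removed
mass originates from the intracellular pool — plasma creatine is buffered
by a large maintained intracellular store, so the dialyzer drains cells,
not just plasma. `analysis/03`–`05` continue with excretion rates (urinary
losses contribute only a few percent of daily creatine removal, ~30% for
creatinine), the PEW phenotype table, and the logistic grid, e.g.

```
sex-adjusted creatine odds ratios (per halving):
  hypoalbuminemia  OR  7.54 [2.38–23.91]  p=0.001 *
  severe_fatigue   OR  4.33 [1.66–11.28]  p=0.003 *
```

— lower plasma creatine associates with higher odds of the planted
outcomes, recovering the generator's true effects.

The same pipeline runs from a shell on any cohort tables with the
documented schemas:

```sh
creapew all --patients patients.csv --sessions sessions.csv --out results/
```

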