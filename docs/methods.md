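# Methods

## Scope and model

The package quantifies single-session solute removal in hemodialysis and
derives protein-energy-wasting (PEW) phenotype variables from it. All
estimators operate on per-patient tables: pre/post plasma concentrations
(μmol/L), total spent-dialysate volume (L) and concentration (μmol/L),
and two 24-h urine collections for patients with residual diuresis
(> 200 mL/24-h).

### Mass-balance partition

Per solute and session,

```
total      = V_dialysate · D_X                         (μmol)
EC loss    = P_pre · ECV_pre − P_post · ECV_post        (μmol)
IC loss    = total − EC loss                            (μmol)
```

The partition assumes the solute diffuses freely in the extracellular
fluid, so the plasma concentration times the extracellular volume is the
extracellular mass. The intracellular loss is a *remainder*, not a
measurement: conservation `total = EC + IC` holds to machine precision by
construction, and a test asserts it. Negative estimated components
(possible when plasma rises intradialytically, or when ultrafiltration
shrinks the ECV faster than the concentration falls) are retained and
flagged per record, never truncated — summaries include them.

ECV comes from anthropometry. The primary formula is
`ECV (L) = √(weight kg) · height (m)`; with cohort-typical inputs
(80 kg, 1.75 m) this gives 15.7 L, about 20% of body weight, and agrees
within 10% with the sensitivity formula
`ECV = weight^0.6469 · height_cm^0.7236 · 0.02154` (15.4 L at the same
inputs). The primary formula is a verbal prescription whose unit
convention is ambiguous; the (kg, m) reading is adopted because the
alternative (height in cm inside the square root) produces a physically
impossible ~118 L. The formula choice is a single config switch
(`ecv_formula: abraham|bird`) and is recorded on every estimate.

### Summaries

Cohort summaries are shown overall and stratified by sex. Dispersion
presentation (mean ± SD vs median [IQR]) follows a Shapiro–Wilk screen at
α = 0.05 per solute/quantity, overridable per solute via
`normality_override`, since no single rule fits all solutes (creatine is
strongly right-skewed, creatinine is not). Paired contrasts (pre vs post,
EC vs IC) use the paired t-test when differences pass the same screen,
else the Wilcoxon signed-rank test; male vs female uses the t-test or
Mann–Whitney U. Proportional decreases are summarised as the mean of
per-patient ratios — the ratio of cohort means is a different (and
wrong) number on skewed data, and a test demonstrates the discrepancy.

### Excretion rates

`dialysate rate = V·D·n/7` with n ∈ {2, 3} sessions/week (other values
are accepted with a warning; the formula is general). Patients without
residual diuresis get a urinary rate of exactly 0 rather than missing,
because the combined rates (CER, CUER) must be defined for every patient.
The urinary contribution uses the combined (urinary + dialysate)
denominator and is summarised as the mean of per-patient fractions.

### Phenotype variables

- **SMI** (kg/m²) = CER · (22.73/8.84) / height², with CER in mmol/24-h
  (dialysate + urinary creatinine).
- **Protein intake** (g/kg/24-h) = `(6.25·(0.028·CUER + 0.031·BW) + UPE)/BW`,
  BW = postdialysis weight; UPE defaults to 0 when urine protein is
  unmeasured (logged per patient).
- **Kt/V** = `−ln(R − 0.008·t) + (4 − 3.5·R)·UF/W` (second-generation
  single-pool form). The source prescription is typographically ambiguous
  (an unbalanced parenthesis); the universally published grouping is
  implemented.
- **CIS fatigue** — sum of the 8-item fatigue-severity subscale of the
  20-item Checklist Individual Strength (range 8–56). The default item
  map is (1, 4, 6, 9, 12, 14, 16, 20) with the positively phrased items
  (6, 12, 20) reverse-scored; because published scorings vary, the item
  map and reverse set are configuration, not constants.
- **Flags** — strict `<` for the four deficit cutoffs (SMI 10.76/6.76 by
  sex, protein 0.8, albumin 38, BMI 23) and inclusive `≥ 35` for fatigue.
  All thresholds live in one config block.

### Association layer

Predictors are scaled so odds ratios read per *decrease*: negated z-score
(per 1-SD decrease) for arginine, GAA and creatinine; negated log2 (per
halving) for the right-skewed creatine. The SD is computed on the
analysis sample after exclusions, recomputed per sensitivity variant.
Fits are plain maximum-likelihood logistic regressions; confidence
intervals are Wald on the log-odds scale with two-sided Wald p values
(chosen for determinism over profile likelihood). No multiplicity
correction is applied; two-sided p < 0.05 is the significance convention.

At n ≈ 59 with up to ~8 covariates, separation is a real possibility.
Separation is detected (non-convergence, |coef| > 20 or SE > 100) and
raised as an explicit error; in the model grid such cells are recorded
in-table and the grid continues. A Firth (Jeffreys-prior) penalized fit,
implemented by adjusted Newton scoring, is available behind `firth: true`
but is off by default because the primary analysis reports plain ML
estimates. A duplicated/collinear covariate raises a rank-deficiency
error rather than silently proceeding.

## The synthetic cohort generator

The generator exists to give every estimator a ground truth; it emulates
the statistical structure the analysis assumes, not full physiology.

### Session kinetics

Per patient/solute, a two-pool model is stepped with explicit Euler
(default dt = 0.5 min; tests use 0.1 min where tolerances demand):

```
d(Ce·Ve)/dt = −Kd·Ce − Quf·Ce + Kc·(Ci/λ − Ce)
d(Ci·Vi)/dt = G − Kc·(Ci/λ − Ce)
dVe/dt      = −Quf
```

Volumes: Ve is the true extracellular volume (the anthropometric estimate
times ~8% lognormal noise), Vi ≈ 0.58·weight − Ve. Ultrafiltration
removes volume from Ve only; convective removal uses sieving coefficient
1 (configurable). Generation G enters the intracellular pool (creatine
and creatinine are produced in muscle); a constant optional
`generation_boost` models an intradialytic proteolysis surge (off by
default).

The partition coefficient λ is the key extension over the classic
two-pool urea model (λ = 1): solutes like creatine hold intracellular
concentrations orders of magnitude above plasma via active transport, so
the pools are taken to be at flux equilibrium when `Ci = λ·Ce`, and a
falling plasma level drives an intra- to extracellular shift. Without λ a
passive `Kc·(Ci − Ce)` flux would make plasma *rise* toward the
intracellular level during dialysis, which is not what is observed.

Mass is conserved exactly by the Euler bookkeeping (initial + generated =
final + dialysate); a property test requires ≤ 0.1% and observes machine
precision. With λ = 1, huge Kc, no UF and no generation the model
collapses to a single pool of volume Vi + Ve with exponential washout;
a test requires ≤ 1% agreement with the closed form at dt = 0.1 min.
Because `P_pre·Ve_pre − P_post·Ve_post` equals the true extracellular
mass change identically, the pipeline's intracellular-loss estimate (with
true volumes supplied) equals the true IC→EC transfer ledger-exactly; the
recovery test requires ≤ 2%.

### Default study conditions

Cohort structure: n = 59, 63% male, 95% thrice-weekly, mostly 4-h
sessions, dialysate volume ~N(135, 27) L, 54% residual diuresis,
UF ~1.9 ± 0.9 L, access mix 22/32/32/14%, albumin ~N(40, 3.5) g/L,
hs-CRP and vintage lognormal. Per-solute kinetics were set once to
realistic hemodialysis scales — predialysis plasma ~77 μmol/L arginine,
~1.8 GAA, ~26 creatine (lognormal, higher in females), ~690 creatinine,
~24 mmol/L urea; dialyzer clearances 110–210 mL/min; λ ≈ 150 for
creatine (large maintained store, small EC share of losses), ≈ 1 for
creatinine/urea. Measured concentrations carry 4% lognormal assay noise;
urine collections are two replicates with 15% CV around a patient-level
true rate derived from an effective residual clearance (≈ 5 mL/min per
L/24-h of diuresis) times a per-solute renal handling factor
(reabsorption ≪ 1 for arginine/creatine, ≈ 1 for creatinine, secretion
for GAA).

Outcomes are Bernoulli draws from `logit⁻¹(α + Σβ·x)` on the *centered*
transformed predictors (centering fixes baseline prevalence without
changing the slopes); the true coefficients — e.g. log(3.2) per halving
of creatine for severe fatigue, zero everywhere for GAA — and the scaling
used are recorded in the truth ledger. CIS items are constructed to match
the drawn severe-fatigue outcome, so the questionnaire path and the
outcome path agree; the other four generated outcome columns are the
coefficient-driven validation targets, while the phenotype table computes
the observational flags from the simulated measurements.

What the generator does **not** emulate: post-dialysis rebound, access
recirculation, protein binding, acid–base coupling, intra-patient
session-to-session variability, and realistic correlation between the
physiologic flag path and the generated outcome columns. Passing tests
therefore demonstrate estimator correctness under the stated model, not
clinical validity on real cohorts.

## Numerical and design choices

- Internal canonical unit is μmol for all solutes; creatinine (and urea
  for CER/CUER) convert to mmol only at the presentation layer.
- Compartment shares are rounded half-up to integer percent at
  presentation only; raw shares sum to 100 exactly.
- Euler stepping halves dt internally (≤ 6 times) if a step would drive a
  mass negative, then fails loudly; nothing is clipped silently.
- Wilcoxon on an all-zero difference vector is defined as p = 1.
- Tables are plain CSV (UTF-8, header row) with unit suffixes in every
  numeric column name; readers treat a recognizable stem with a wrong
  unit suffix as an error, never as a conversion.
- Problem sizes in the validation suites (20-patient noise-free cohorts
  at dt = 0.1 min; 200 replicate fits at n = 500 for logistic
  bias/coverage; 600-patient cohorts for grid power checks) were chosen
  as the smallest sizes at which the tested tolerances are meaningful.

## Known limitations

- The intracellular loss inherits all error in the anthropometric ECV;
  with real (noisy) ECV estimates the 2% recovery bound does not apply —
  it is a correctness bound, not an accuracy claim.
- The Abraham-formula unit reading, the CIS item map and the urinary
  contribution denominator are documented interpretations of verbal
  prescriptions; all are configurable.
- Plain ML logistic fits at n ≈ 59 with the full covariate set can
  separate; affected grid cells are reported as errors by design.
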