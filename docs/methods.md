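# Methods

## The problem

Tulathromycin is a long-acting macrolide labelled for cattle and swine and
used extra-label in goats. There is no regulatory milk tolerance for it in
goats, so any detectable residue in milk is violative and the assay limit of
detection (LOD) acts as the de-facto tolerance. `lactopk` models the
depletion of tulathromycin in plasma and of its marker residue CP-60,300 in
milk of lactating goats after one or two subcutaneous (SC) 2.5 mg/kg doses,
and estimates how many days after the last injection the upper band of the
population distribution falls below the LOD (1.2 ng/mL plasma, 1.8 ng/mL
milk).

## Structural model

A two-compartment disposition model with first-order absorption from an SC
depot and a cumulative milk-excretion compartment:

    dAa/dt    = -Ka Aa
    dA1/dt    =  Ka Aa - Cl C - Cl2 (C - C2) - CLmilk C
    dA2/dt    =  Cl2 (C - C2)
    dAmilk/dt =  CLmilk C,      C = A1/V,  C2 = A2/V2

Amilk is purely cumulative (no back-transfer), so the plasma subsystem is an
ordinary two-compartment model whose total central elimination clearance is
`Cl + CLmilk`; the fraction of the dose ultimately excreted in milk is
`CLmilk/(Cl + CLmilk)` (about 4 % at the reference estimates). The system is
linear, so multiple doses superpose. The analytic tri-exponential solution
(partial-fraction coefficients over the hybrid rate constants alpha, beta
and Ka) is the production path; `solve_ode` integrates the same equations
at `rtol 1e-10` and is used purely as an independent oracle — the suite
requires agreement within 1e-6 relative over two-dose profiles for random
positive parameter sets, and conservation of dose mass across depot,
compartments, milk and the eliminated integral within 1e-6.

Numerical edge cases: `Ka` exactly coincident with alpha or beta (relative
gap below 1e-9) is handled by a 1e-8 relative nudge of `Ka` rather than the
confluent closed form — the case has measure zero and the ODE oracle is
unaffected. The one-compartment variant is the `Cl2 = 0` reduction (the
vanishing slow exponent's coefficient is exactly zero); the
three-compartment variant adds a second peripheral pair and is solved by
eigendecomposition of the full linear system.

## Noncompartmental analysis

Cmax/Tmax are read off the observed points; lambda-z comes from the
best-fit rule — among contiguous terminal windows of at least three positive
concentrations excluding Tmax, maximise the adjusted R^2 of the log-linear
regression, ties (within 1e-4) to the longer window. This mirrors the
common WinNonlin default; the published analysis names the software but not
the rule. AUC uses the linear trapezoid by default, with linear-up/log-down
available; `AUCinf = AUClast + Clast/lambda_z`. On the published average
curves the linear rule reproduces the published plasma AUClast (second
injection, dose anchored at 168 h with zero concentration) within 0.03 %
and the milk AUClast (first injection, 0–168 h) within +0.54 %, while
log-down lands 0.92 % below it — the two variants bracket the published
value, which is consistent with per-animal log-down NCA averaged over
subjects; the exact published method is not recoverable.

## Population model and estimation

Individual parameters are log-normal around the population means,
`P_i = theta exp(eta_i)`, `eta ~ N(0, Omega)` with diagonal Omega (the
reference table reports one IIV per parameter and no covariances).
Residual error is proportional by default for both observation kinds —
plasma concentrations and cumulative milk amounts — with additive and
combined forms available for the error-model comparison. Market-age
subjects contribute plasma likelihood only; lactating subjects contribute
plasma and milk simultaneously.

The marginal likelihood is approximated subject-by-subject by the
Laplace/FOCE method with interaction: the joint -2 log-likelihood is
minimised over each subject's eta by a damped Newton iteration whose
curvature matrix is the Gauss-Newton Hessian `Omega^-1 + J' W J` (W the
inverse residual variances evaluated at the conditional prediction), and
the Gaussian integral is replaced by the log-determinant correction at the
mode. With all omegas zero this reduces exactly to the pooled -2LL — the
suite asserts bit-exact equality — and on one- and two-eta problems it
agrees with mode-centred Gauss-Hermite quadrature to well within 2 %.

The outer problem optimises log-theta, log-omega and log-sigma with
L-BFGS-B (finite-difference step 1e-4 on the log scale, relative objective
tolerance 1e-6, at most 200 outer iterations by default), warm-starting
each subject's eta from the previous evaluation. Starting values come from
an NCA heuristic (clearance from dose/AUCinf, volume from clearance over
lambda-z, milk clearance from the excreted fraction). Model selection is
by AIC, with -2LL and BIC reported.

The published IIV column does not state whether it is the variance or the
SD of the log-scale random effect; the package default reads it as the
variance (`iiv_scale="variance"`), a switch provides the SD reading. The
variance reading is also the one whose simulated population bands are
consistent in magnitude with the published withdrawal estimates; the SD
reading roughly doubles them. Between-occasion variability is not
modelled: the final published model does not contain it, and the second
injection is pure superposition with the same individual parameters.

BLOQ observations default to exclusion from the likelihood (M1), the usual
default of the software the published analysis used, which states no policy;
`zero` and `half_lod` policies are provided.

## Bootstrap

Model evaluation uses a nonparametric subject bootstrap: subjects are
resampled with replacement stratified by study label, so each replicate
keeps the original per-study counts (unstratified resampling could produce
replicates with no milk data at all). CIs are empirical 2.5/97.5
percentiles over converged replicates (percentile method; with 100
replicates BCa refinements are not meaningful). Failed replicates are
excluded and counted; more than 50 % failures aborts.

## Monte Carlo simulation and withdrawal time

Each replicate draws one individual from the population model and
evaluates the closed-form plasma and cumulative-milk trajectories for an
88-kg subject (the study mean weight) on a 12-h grid; milk concentrations
are reconstructed per milking by dividing interval excreted amounts by the
milk volume produced over the interval (default 10.8 lbs/day, the study
mean yield, split over twice-daily milkings at 12-h spacing, density
1.03 g/mL). The "upper limit of the 95 % confidence interval" is
implemented as the 95th percentile of replicate values (the published
figure legend plots the 95th and 50th percentiles); a 97.5th-percentile
option exists. The withdrawal time is the first whole day after the last
dose from which the band stays below tolerance at every later grid time.
The replicate band reflects inter-individual variability only; a flag adds
the proportional assay-error layer.

Milk withdrawal estimates are computed but flagged non-definitive: the
reconstructed terminal milk concentrations fluctuate with milking volume
(and the marker residue pools parent and metabolites), which is exactly why
the published analysis declined to fix a milk withdrawal time.

With 100 replicates the 95th percentile is an order statistic of a heavily
right-skewed distribution (the absorption rate constant's IIV is enormous,
so a few replicates show extreme flip-flop kinetics with terminal
half-lives of weeks); its withdrawal day varies across seeds with an SD of
roughly a week. `scripts/acceptance.py` therefore reports the mean day
over 96 independent 100-replicate simulations. At the reference
parameters this expected day is about 44–46 for a single dose and 51–53
(after the second injection) for the two-dose regimen; the corresponding
published point estimates are 43 and 62 — the single-dose value is
reproduced, the two-dose value is not reproducible from the published
model under any fixed percentile of the superposed system (the asymptotic
95th-percentile crossings are day 46 and day 53: no percentile choice
yields a 19-day gap between regimens), and plausibly reflects Monte Carlo
noise of a single 100-replicate draw or occasion-specific absorption not
present in the final published model.

## Synthetic data generator

The generator emulates the three pooled source designs — two-dose
lactating (n=8, body weight 73–109 kg, doses at 0 h and 168 h),
single-dose lactating (n=8, 72.5–89 kg) and market-age (n=10, dense 1-min
to 360-h plasma-only schedule) — with body weights and daily milk yields
uniform over the published ranges (no distributional detail is published),
twice-daily milkings anchored 12 h post-dose (matching the published
average table's grid rather than literal clock times), proportional assay
noise (0.485 plasma, 0.0234 on cumulative milk amounts) and BLOQ flags
from the assay limits. Market-goat body weight is not published anywhere;
30 kg (range 25–35) is a stand-in typical of 6-month meat goats and is
configurable. Per-milking volumes are a modelling stand-in derived from the
daily yield, so milk-matrix averages match the published table only in
structure, not point-by-point.

What passing tests show, and do not show: parameter recovery and bootstrap
coverage results on these synthetic datasets demonstrate the estimator's
correctness under the model's own assumptions (log-normal IIV, proportional
noise, exact sampling compliance); they say nothing about model
misspecification, assay drift, missed milkings or covariate structure in
real animals, and the published observation counts cannot be reconstructed
exactly from the published schedules.

## Problem sizes used in the shipped tests

Tests run the pooled 26-subject fit once at 150 outer iterations (a few
minutes), bootstrap determinism on 6-subject datasets with 2–3 replicates
at reduced iteration caps, and simulation checks at 100 replicates;
closed-form-vs-ODE properties use 100 random parameter sets. These sizes
exercise every code path at full fidelity of the algorithms while keeping
the suite practical to run routinely.

## Known limitations

- No saturable elimination, enterohepatic recirculation or protein-binding
  submodel; no covariates (none could be included in the published analysis).
- No SAEM/MCMC estimator and no omega covariances.
- The regulatory 99th-percentile tolerance-limit machinery for official
  withdrawal times is out of scope; the percentile-band rule here mirrors
  the published analysis, not FDA/EMA guidance.
- Exact reproduction of the published parameter table by refitting is
  impossible without the raw individual-animal data; that table serves as
  generator ground truth and fixture.
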