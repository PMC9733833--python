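# Methods

This note documents the model, the estimation machinery, the synthetic
cohort that stands in for the clinical dataset, and the numerical and
design choices a maintainer would want to know about.

## The model

Valproic acid (VPA) serum concentration after oral maintenance dosing is
described by a one-compartment model with first-order absorption and
elimination at steady state.  Because all concentrations are oral
troughs, clearance and volume are apparent (CL/F, V/F) and the
absorption rate constant cannot be identified; Ka is fixed at 1.9 h⁻¹.
The steady-state concentration t hours after a dose D given every τ
hours is the standard superposition closed form

    C(t) = D·Ka / (V·(Ka − ke)) · [ e^(−ke·t)/(1 − e^(−ke·τ))
                                    − e^(−Ka·t)/(1 − e^(−Ka·τ)) ],   ke = CL/V,

with an analytic L'Hôpital limit used when |Ka − ke|/Ka < 1e-9.  The
trough is C(τ).

Typical clearance carries the covariate model.  The final pediatric
model is

    CL/F = θ_CL · (AGE/5)^θ_age · θ_AG^[AG] · θ_GG^[GG],     V/F = θ_V,

where [AG], [GG] indicate the ABCB1 rs3789243 genotype (AA reference).
Defaults: θ_CL = 0.214 L/h, θ_V = 3.63 L, θ_age = 0.357, θ_AG = 0.953,
θ_GG = 1.08.  The age term is a power model on age normalized to a
reference of 5 years: at that near-median age the typical CL/F (0.214)
then sits next to the covariate-free base value (0.205), which an
unnormalized power model would not reproduce.  The reference age is
configurable.

Individual clearance is log-normal, CL_i = TVCL·exp(η), η ~ N(0, ω²),
with ω the *standard deviation* of η (ω = 0.169 in the final model, i.e.
≈17% CV; the alternative variance reading would imply an implausible
41% CV).  Residual error is additive on the concentration scale
(σ = 11.9 mg/L); proportional and combined error models are available.
Bioavailability F is never a separate parameter.

## Estimation

With a single random effect the subject marginal likelihood is a 1-D
integral and is computed essentially exactly by adaptive Gauss–Hermite
quadrature (41 nodes by default) centered at the conditional mode of η
with curvature-based scaling.  The conditional mode is found by a
damped, backtracking Newton iteration vectorized across subjects
(central finite differences, tolerance 1e-10).  A FOCE-I engine — the
classical first-order conditional linearization with
interaction — is provided for fidelity comparisons; on well-behaved
data the two agree within ~1 OFV unit, and the quadrature engine is
the reference.

The objective function value is OFV = −2·log marginal likelihood.
Optimization is quasi-Newton (L-BFGS-B) on log-transformed scale
parameters (typical values, multipliers, ω, σ), so positivity needs no
explicit constraints; exponents and slopes are unconstrained.
Non-convergence sets a flag rather than raising, so bootstrap
replicates can count failures.  Relative standard errors come from the
central finite-difference Hessian of the OFV at the optimum
(cov = 2·H⁻¹); a non-positive-definite Hessian reports RSEs as
missing.  Empirical Bayes estimates are conditional modes;
η-shrinkage = 100·(1 − SD(η̂)/ω) and ε-shrinkage = 100·(1 − SD(IWRES)).
CWRES uses the FOCE linearization around η̂: the residual vector
against the linearized marginal mean is decorrelated by the inverse
matrix square root of V_i = ω²FF' + R.

IIV on V/F is not modeled: trough-only data identify it too poorly
(the original analysis dropped it for the same reason).

## Covariate selection

Stepwise forward inclusion / backward elimination on CL/F only.
Continuous candidates (AGE, WT, daily dose) are tried as linear, power,
exponential and piecewise (two-slope) effects centered at age 5 y,
weight 20 kg and the median daily dose; categorical candidates (sex,
co-medications above a 2.5% usage threshold, genotypes passing the
Hardy–Weinberg screen) as per-level multipliers.  A term enters when it
drops the OFV by more than the χ² quantile for its degrees of freedom
at p < 0.05 (3.84 for 1 df, 5.99 for a joint 2-df genotype term) and is
eliminated when its removal costs less than 6.635 (p < 0.01).  The
backward cut is deliberately flat across df: a df-adjusted backward cut
(9.21 at 2 df) sits exactly on the typical OFV contribution of the
rs3789243 term at this sample size and makes retention a coin flip,
producing add/remove oscillation.  `run_stepwise` also stops if a
covariate set recurs at the end of a cycle, keeping the parsimonious
post-elimination state.  Candidate fits start from the current
estimates; ties break by lower AIC, then fewer parameters.

Two behaviors of likelihood-ratio selection worth knowing: with
age–weight correlation r ≈ 0.9 the criterion usually admits exactly one
of the two, but a ~5–10% per-dataset chance remains that the second
clears the entry cut by noise and survives elimination — absolute
"never both" cannot be guaranteed by any threshold rule, which is why
the original analysis excluded weight manually.  And trying four
functional forms per covariate inflates the per-covariate type-I rate
above the nominal single-test 5%.

## Model evaluation

The bootstrap resamples subjects (not observations) with replacement to
the original subject count, preserving within-subject correlation, and
refits each replicate from the reference estimates.  A replicate is
successful when the optimizer converges and (optionally, default on)
the OFV Hessian is positive definite; percentiles (2.5/50/97.5) are
computed over successful runs, and the relative error is
100·(median − reference)/reference.  The VPC re-simulates the original
design with fresh η and ε and overlays observed 5/50/95th percentiles
on the 2.5–97.5% band of each simulated percentile; because the design
is trough-only, bins can be taken on time after dose (narrow) or on
age — both are exposed.  Scaled-down defaults (100–200 bootstrap runs,
200 VPC replicates) are used in the test suite; the full 1,000 is a
flag away.

## Dose simulation

Monte Carlo subgroups (rs3789243 genotype × age bin, n = 10,000 by
default) are dosed at 15–35 mg/kg/day split q12h; weight comes from a
growth-reference median weight-for-age table (anchors from 0.5 to 15 y,
linearly interpolated, clamped to 10–40 kg in the dosing grid).  The
national survey behind the original dosing table is not public, so the
table here is a stand-in calibrated to realistic pediatric medians;
absolute PTA percentages are therefore not comparable
number-for-number to the original grid, only their direction across
age, dose and genotype.  PTA is the percentage of simulated troughs
inside 50–100 mg/L; a regimen is adequate at PTA ≥ 70%.  Residual
(assay) error is excluded from simulated troughs by default — PTA
describes true exposure, not noisy measurements — with a flag to
include it.  Dose recommendations use the minimal adequate dose by
default; a max-PTA variant is provided because the originally stated
recommendation for GG children aged 2–3 y (30 mg/kg/day) corresponds
to that rule rather than to the minimal-dose rule.

One analytic caveat documented here because it is easy to mistake for a
bug: with CL ∝ age^0.357, the trough at a fixed mg/kg/day dose is
U-shaped in age (minimum near 2–4 y, equivalently ~18 kg) for *any*
realistic monotone weight-for-age curve, because relative weight growth
below ~2.5 y is slower than relative clearance growth.  PTA rows at a
fixed dose therefore dip slightly over the youngest bins before the
strong age trend takes over, and trough-vs-weight curves rise strictly
only above ~20 kg.  The package asserts the robust directional
properties (oldest bin attains most at the lowest dose and least at
the highest; GG ≤ AG at low doses; strict weight monotonicity above
20 kg; mean trough > 100 mg/L at 40 mg/kg/day above 20 kg).

## Synthetic cohort

The generator emulates the study cohort: 103 children, 2–5 troughs each
(mean 3.65, ≈376 total), ages from a truncated log-normal solved
numerically to hit mean 5.30 / SD 3.39 on [0.5, 15] y, weights from the
growth-reference curve with 15% log-normal noise truncated to
[6.5, 52] kg, daily doses from a truncated normal (mean 23.8, SD 5.7,
range [9.9, 45.7] mg/kg/day) rounded to practical 5 mg administrations,
sex at the study ratio, genotypes drawn under Hardy–Weinberg
equilibrium at the cohort's allele frequencies for all 15 panel SNPs,
and co-medication flags at the reported rates.  Troughs are generated
from the final model (η per subject, additive ε per observation);
values below the 1 mg/L quantification limit are resampled and counted.

Two design conditions matter for identifiability and were chosen after
profiling the likelihood:

* **Regimens are a bid/tid mix** (q12h, with a third of subjects q8h),
  as in the study population, which took the drug two to three times a
  day.  With every subject on an identical q12h schedule, θ_V is
  unidentifiable from troughs: the profile OFV decreases monotonically
  toward V → ∞ (where the trough degenerates to dose/(CL·τ)) and drags
  θ_CL up ~50% along the ridge.
* **Sampling times fall in a 2 h pre-dose window** (TIME_H ~ τ − U(0,2)),
  as in retrospective TDM where troughs are drawn before, not at, the
  scheduled dose.  With both conditions the replicate spread of the
  estimator matches the reported precision of the original fit
  (θ_CL ≈ 6% vs the printed RSE 7.4%; θ_V interior optimum with
  ≈20–50% spread vs printed RSE 23.8%).  With neither, the original
  covariance step could not have succeeded.

What the generator does **not** emulate: TDM titration feedback (doses
are drawn independently of individual clearance, so simulated
concentrations spread wider than the clinical 14.7–111 mg/L range and
average ≈70–80 mg/L rather than 60.5 — the generator's information
content is conservative in the right direction for recovery studies);
occasion-to-occasion dose changes; within-subject growth;
pharmacokinetic drug–drug interactions (none survived selection in the
original analysis).  Passing recovery tests therefore shows the
estimator recovers the generative process at study size and design,
not that the clinical dataset itself would be recovered.

## Problem sizes in the checks

The test suite and the acceptance script run at study scale: 103
subjects per cohort, 10 replicate refits for recovery medians, 20
replicates for stepwise operating characteristics, 100 bootstrap
replicates, 200 VPC simulations, and n = 10,000 virtual subjects per
PTA cell.  These sizes were chosen so every check completes in minutes
on one CPU while keeping Monte Carlo error well below the asserted
margins (binomial SE < 0.5 percentage points at n = 10,000).

## Known limitations

* Trough-only data identify V/F weakly even under the mixed design; its
  single-replicate estimate is volatile (the median over replicates is
  the meaningful recovery quantity).
* RSEs come from a finite-difference OFV Hessian and match
  covariance-step values only in order of magnitude.
* The HWE screen deliberately uses the plain Pearson chi-square with
  df = 1, no continuity correction and no exact test, even at expected
  counts ≪ 5 (a warning is logged) — this is the unique choice
  consistent with the cohort's printed p-values.
* No prediction-corrected VPC, no inter-occasion variability, no
  multiple correlated random effects, no external validation.
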