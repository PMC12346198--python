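# Methods

## Structural models

Both analytes — the valine-ester pro-drug and its parent drug — follow
linear two-compartment disposition with first-order elimination from the
central compartment, parametrized as clearance CL (L/h), central volume
V_c (L), intercompartmental clearance Q (L/h) and peripheral volume V_p
(L). Oral dosing adds a depot with first-order absorption rate K_a (1/h)
and bioavailability F. IV administration is modelled as a bolus into the
central compartment: sampling from 5 minutes post-dose is consistent
with bolus dosing, and no infusion information exists, so an infusion
option is deliberately omitted.

The combined pro-drug → parent model couples two such blocks. The
pro-drug's elimination flux (CL/V_c)·A_central splits at a single node:
a fraction Fm enters the parent's central compartment mol-for-mol, and
the remaining 1 − Fm leaves the system irreversibly. There is no
presystemic (first-pass) conversion pathway, no back-conversion and no
enterohepatic recycling: conversion is a property of systemic clearance
only. Published figure legends for models of this shape label the
compartments inconsistently; this package uses the unambiguous topology
pro-drug {depot, central, peripheral} + parent {central, peripheral},
with parameters named by role (`prodrug.CL`, `parent.CL`, …).

Amounts are µmol of active-moiety equivalents. mg/kg doses are converted
via the compound registry (molar mass × salt factor); molar masses are
configuration inputs, never computed from structures, and the shipped
registry encodes each conjugate's mass basis as parent mass × the
dosed-form ratio implied by the molar-equivalent study doses
(56.4/40 = 1.41 and so on).

## Solving the system

The models are linear constant-coefficient ODEs, so no numerical
integrator is used: compartment amounts are exp(At)·x0, evaluated by
eigendecomposition of the (stable, Metzler) rate matrix, with a
matrix-exponential fallback when the eigenvector matrix is
ill-conditioned (e.g. K_a coinciding with a disposition eigenvalue).
This is exact to floating-point accuracy; tests verify agreement with
the textbook bi-exponential and Bateman closed forms at 1e-6 relative
and mass balance (amounts + cumulative elimination = absorbed dose) at
1e-8.

## Estimation

The reference estimator for data of this kind is a non-linear
mixed-effects (population) fit. With three animals per arm, this package
instead implements **naive-pooled maximum likelihood**: one typical
parameter vector fitted to all animals' data at once, with
between-animal variability present only in the data-generating
simulator. This is a deliberate, documented simplification; the
recovery experiments (below) quantify what it costs under the study
designs of interest.

- **Objective.** Proportional residual error is handled by
  log-transforming both sides: minimise Σ(log y − log f(θ))², the exact
  ML fit under multiplicative log-normal noise and a close approximation
  to a proportional-error likelihood at assay-level CVs.
- **BLQ records.** Observations below the lower limit of quantification
  are not discarded: each adds a one-sided hinge residual
  max(0, log(f(θ)/LLOQ)), penalising predictions above the limit — a
  least-squares surrogate for censored (M3-type) likelihood. This is
  what makes an all-BLQ parent profile informative: simulated studies
  with Fm = 0 are recovered at Fm ≤ 0.02 rather than leaving Fm
  unidentified. (NCA uses the simpler conventional rule: leading BLQ set
  to 0, trailing BLQ dropped.)
- **Transforms and bounds.** Positive parameters are searched on the log
  scale and fractions (F, Fm) on the logit scale, with all parameters
  bounded to [1e-6, 1e6] in natural units; every iterate is therefore
  structurally valid. Optimisation is trust-region-reflective least
  squares (ftol/xtol/gtol 1e-10) from 5 (single-analyte) or 3 (combined)
  jittered starts with a fixed seed; standard errors come from J'J via
  the delta method, and bound-hitting parameters are flagged.
- **Two stages.** Per-analyte fits (pro-drug data after pro-drug dosing;
  parent data from the parent-only arm) seed the combined fit, which
  re-estimates everything jointly plus Fm. The parent-only arm is an
  identifiability requirement: without it, Fm and the parent volume
  trade off freely, and the code warns accordingly. Initial values are
  data-informed (dose/AUC for CL, dose over first concentration for
  V_c).

A known small-sample pathology: with a 12 h window and a terminal
half-life of several hours, occasional noise draws support CL → 0 (all
apparent loss explained as distribution). Such fits end at the search
bound or with enormous CL standard errors; they are flagged, and the
recovery experiments screen them out (below) rather than average them.

## Non-compartmental analysis

Linear trapezoidal AUC throughout — the simplest defensible default; the
function is separate and switchable if a lin-up/log-down variant is ever
needed. When a dose event is supplied, the dose-to-first-sample gap is
closed the standard way (log-linear back-extrapolated C0 for IV bolus,
C(0) = 0 for oral). λz comes from log-linear regression on the terminal
window with the best adjusted R² among candidates of ≥ 3 positive points
excluding Tmax; AUC_inf = AUC_all + C_last/λz; CL = dose/AUC_inf for IV;
F is the dose-normalized PO/IV AUC ratio. Group summaries are geometric
means with geometric CV √(exp(s²) − 1).

## Dose-response and stability

IC50 curves use the unit-Hill-slope three-parameter logistic
Y = Bottom + (Top − Bottom)/(1 + X/IC50), fitted by non-linear least
squares with IC50 on the log scale, which yields the multiplicative
asymptotic 95% CI that such assays report. Vehicle (zero-concentration)
wells are legal and anchor Top. Estimates at or beyond the top tested
concentration are reported as ">max" with CI "not determined"
(boundary inclusive).

Plasma stability uses raw signal ratios for percent remaining (no
fitting), log-linear regression for the first-order disappearance rate
(non-positive slopes reported as "stable"), and last-timepoint parent
signal over baseline for the formation fold (LLOQ-substituted when the
baseline is zero, flagged). A conjugate with ≥ 90% remaining and fold
≤ 1.2 is flagged "no conversion" — the signature of an ester that plasma
esterases do not touch. Both the endpoint and whole-course minimum
percent remaining are reported, since "≥ 90% remaining" can be read
either way.

## Synthetic studies

The generator emulates single-dose serial-sampling mouse PK studies:
n = 3 animals of 0.030 kg per dose group; IV sampling at 0.083, 0.25,
0.5, 1, 2, 6, 12 h and PO at 0.25, 0.5, 1, 2, 4, 8, 12 h (variants
dropping the 1 h or 4 h draw and adding 24 h are provided); log-normal
between-animal variability (default 20% on CL and V_c — which
parameters carry it is not otherwise constrained); multiplicative
proportional residual error (default 15%, a plausible bioanalytical CV,
not a measured one); censoring below an LLOQ of 0.01 µmol/L. Triplicate
dose-response plates use half-decade (semi-log) concentration series
with proportional noise; stability timecourses are mono-exponential
decay at 0–360 min with parent appearance as a molar fraction of
consumed pro-drug. One seeded generator drives each dataset; the seed
is recorded in metadata.

What the simulator does **not** reproduce from real data: absorption
delays and double peaks, non-linear (saturable) kinetics, assay-specific
error structure (additive + proportional), enterohepatic recycling, or
presystemic conversion. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to these
violations.

## Reference scenarios and recovery experiments

The concentration data behind the motivating studies are unreleased, so
reported *typical estimates* serve as simulation truths: conversion
fractions 0.23 (valine–niclosamide) and 0.39 (valine–compound #11);
IV clearances 0.08 L/h (niclosamide), 0.03 L/h (compound #11),
0.02/0.004 L/h (their conjugates); SNU475 niclosamide IC50 1.33 µM.
Volumes, K_a and F were never reported; the scenario values are fixed
package defaults chosen once to be plausible for a mouse and consistent
with the printed exposures: central volumes of 0.15 L (parents, moderate
distribution) and 0.008 L (conjugates, polar and plasma-restricted),
peripheral pools sized so distribution and terminal phases resolve
within the sampled 12 h window (a prerequisite for the original designs
to have been fittable), and oral bioavailabilities back-calculated from
the printed oral AUCs (e.g. F = 0.27 for valine–niclosamide from
48.57 h·µmol/L; F ≈ 0.005 for valine–compound #11 from 4.17 h·µmol/L,
its solubility-limited absorption).

Each recovery experiment simulates replicate studies, fits each one, and
aggregates after a convergence/covariance screen (bound-hitting fits and
fits with relative standard errors above 100% for CL, 50% for Fm, are
excluded — the standard practice in simulation studies):

- **Fm**: 5 replicate four-arm studies per scenario, two-stage fit,
  inverse-variance weighted mean of retained estimates (fixed-effect
  pooling across replicates; unweighted median as fallback).
- **CL**: 8 replicate IV cohorts, pooled fit each, geometric mean of
  retained estimates.
- **IC50**: one triplicate plate refit.

Replicate counts are package choices balancing Monte-Carlo stability
against desk-scale runtimes (each replicate is a full study fit);
`scripts/acceptance.py` completes in well under a minute.

## Known limitations

- Naive-pooled estimation understates between-animal information and
  provides no IIV estimates; it recovers typical values adequately for
  n = 3 designs but is not a population analysis.
- The hinge treatment of BLQ records approximates, but is not, a
  censored likelihood.
- Standard errors are asymptotic (J'J) and optimistic at these sample
  sizes; no bootstrap is provided.
- Single-dose only; multi-dose profiles must be built by superposition
  of the linear model.
- The conversion half-life is defined as ln 2/K_met (the formation rate
  constant), and the convertible amount as Fm × systemically absorbed
  dose; both are interpretive choices, stated here because other
  conventions exist.
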