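# prodrugpk

Pharmacokinetic analysis of ester pro-drugs and their active parent drugs,
built around the case of valine-conjugated niclosamide analogs developed
for hepatocellular carcinoma: simulation and fitting of a linked
pro-drug → parent two-compartment model, estimation of the fraction
converted, non-compartmental exposure analysis, dose-response IC50
fitting, and plasma-stability metrics — all exercisable on synthetic data
that emulates small serial-sampling mouse studies.

## The problem

A pro-drug (here, a valine ester of niclosamide) is dosed in the hope
that esterases cleave it in vivo to release the active parent. Whether
that actually happens — and how much of the dose ends up as parent — is a
quantitative question. Given plasma concentration–time data for both
analytes after pro-drug dosing, plus a parent-only dosing arm, a combined
compartmental model can estimate the **fraction converted, Fm**: the
share of the pro-drug's systemic elimination that forms parent drug.

## The model

Each analyte follows a linear two-compartment disposition model
(clearance CL, central volume V_c, intercompartmental clearance Q,
peripheral volume V_p), with a first-order absorption depot (K_a, F) for
oral dosing. In the combined model the pro-drug's elimination flux
splits: a fraction Fm enters the parent's central compartment, the rest
is lost irreversibly:

    depot:            dA0/dt = −Ka·A0                       (PO only)
    pro-drug central: dA1/dt = Ka·A0 − (CL/Vc)·A1 − Q·(A1/Vc − A2/Vp)
    pro-drug periph.: dA2/dt = Q·(A1/Vc − A2/Vp)
    parent central:   dA3/dt = Fm·(CL/Vc)·A1 − (CLp/Vc,p)·A3 − Qp·(A3/Vc,p − A4/Vp,p)
    parent periph.:   dA4/dt = Qp·(A3/Vc,p − A4/Vp,p)

Being linear with constant coefficients, the system is solved in closed
form (eigendecomposition of the rate matrix). Derived conversion
kinetics follow the standard definitions: K_el = CL/V_c of the pro-drug,
K_met = Fm·K_el, conversion half-life ln 2/K_met, amount converted at
completion Fm × absorbed dose, and conversion rate = amount / (5
half-lives).

Estimation is naive-pooled maximum likelihood on log concentrations
(log-transform-both-sides, the least-squares match to a proportional
error model), in two stages: independent per-analyte two-compartment
fits, then a joint fit of all cohorts that estimates Fm on the logit
scale. Below-quantification records contribute one-sided censoring
residuals rather than being discarded.

The package also covers the surrounding assay analytics: NCA (Cmax,
AUC_all, AUC_inf, λz, CL = dose/AUC_inf, bioavailability F as a
dose-normalized AUC ratio), unit-slope three-parameter logistic IC50
fits with log-scale confidence intervals, and plasma-stability summaries
(percent remaining, first-order half-life, parent-formation fold).

## Worked example

Run the full two-stage analysis on the bundled valine–niclosamide
reference scenario (synthetic mouse study: n = 3 per arm, IV 2.8 /
PO 56.4 mg/kg pro-drug plus IV 2 / PO 40 mg/kg parent arms, 20%
between-animal variability, 15% proportional assay error, true
Fm = 0.23):

```bash
$ prodrugpk run --scenario valine_niclosamide --seed 7 --out-dir run7
Fm = 0.211; artefacts in run7
```

The estimated fraction converted from this single simulated study is
21.1% against the 23% used to generate it — the kind of wobble a 3-mouse
design produces. `run7/conversion_metrics.csv` holds the derived
conversion kinetics at the fitted parameters:

```
kel_per_h  fm      kmet_per_h  conversion_half_life_h  amount_umol  rate_umol_per_h
1.886      0.2107  0.3973      1.745                   0.0384       0.0044
```

i.e. the pro-drug is cleared at 1.89 h⁻¹ but only ~21% of that flux
forms niclosamide (K_met 0.40 h⁻¹, conversion half-life 1.7 h).
`run7/nca_summary_parent_only.csv` summarises the parent-only arm by
geometric means, e.g. AUC_all 2.27 h·µmol/L with a 12% geometric CV
across the three IV animals. A run log records the seed and stage
timings; re-running with the same seed reproduces every artefact byte
for byte.

The same pieces are available as a library:

```python
from prodrugpk import scenarios, recovery

study = scenarios.valine_niclosamide_scenario()
prodrug_arms, parent_arms = recovery.simulate_conversion_study(study, seed=7)
combined, stage_pd, stage_pa = recovery.two_stage_fit(prodrug_arms, parent_arms, seed=7)
print(combined.params.Fm)        # 0.211
```

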