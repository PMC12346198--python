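"""Pooled estimation: exact recovery, identifiability, estimator properties."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from prodrugpk.dataset import PKDataset, concat_datasets
from prodrugpk.fitting import combined_objective, fit_combined, fit_single
from prodrugpk.model import ANALYTE_PARENT, ANALYTE_PRODRUG, CombinedModelParams, DispositionParams
from prodrugpk.recovery import simulate_conversion_study, two_stage_fit
from prodrugpk.scenarios import valine_niclosamide_scenario
from prodrugpk.synth import (
    IV_SCHEDULE,
    NOISELESS,
    PO_SCHEDULE,
    ErrorModel,
    StudyDesign,
    generate_pk_cohort,
)


def make_cohorts(params, compound, error, seed, n=3, iv_dose=2.0, po_dose=40.0, lloq=1e-6):
    iv = StudyDesign(route="IV_bolus", dose_mg_per_kg=iv_dose, schedule=IV_SCHEDULE, n_per_group=n, lloq=lloq)
    po = StudyDesign(route="PO", dose_mg_per_kg=po_dose, schedule=PO_SCHEDULE, n_per_group=n, lloq=lloq)
    a = generate_pk_cohort(iv, params, error, compound, seed, subject_prefix="IV")
    b = generate_pk_cohort(po, params, error, compound, seed + 1, subject_prefix="PO")
    return concat_datasets([a, b])


class TestFitSingle:
    def test_noiseless_exact_recovery(self, two_cpt_params, niclosamide):
        """Noiseless IV + PO data return the generating parameters to
        within 0.1% (self-consistency of simulator and estimator)."""
        data = make_cohorts(two_cpt_params, niclosamide, NOISELESS, seed=0, n=1)
        fit = fit_single(data, seed=0)
        assert fit.converged
        for name in ("CL", "Vc", "Q", "Vp", "Ka", "F"):
            est, true = getattr(fit.params, name), getattr(two_cpt_params, name)
            assert est == pytest.approx(true, rel=1e-3), name

    def test_noisy_iv_cohorts_recover_cl(self):
        """n = 3 IV cohorts with study-level noise (20% IIV, 15%
        proportional error) recover CL within 15% after aggregating a few
        replicate cohorts."""
        from prodrugpk.recovery import recover_cl
        from prodrugpk.scenarios import niclosamide_iv_scenario

        res = recover_cl(niclosamide_iv_scenario(), seed=3, n_replicates=5)
        assert res.estimate == pytest.approx(0.08, rel=0.15)

    def test_all_blq_errors(self, two_cpt_params, niclosamide):
        design = StudyDesign(route="IV_bolus", dose_mg_per_kg=2.0, schedule=IV_SCHEDULE, lloq=1e9)
        cohort = generate_pk_cohort(design, two_cpt_params, NOISELESS, niclosamide, seed=0)
        with pytest.raises(ValueError, match="quantified"):
            fit_single(cohort)

    def test_positivity_by_construction(self, two_cpt_params, niclosamide):
        """Log-scale search means estimates are positive whatever the data."""
        data = make_cohorts(two_cpt_params, niclosamide, ErrorModel(0.4, {}), seed=9, n=1)
        fit = fit_single(data, seed=9)
        assert fit.params.CL > 0 and fit.params.Vc > 0 and fit.params.Vp > 0

    def test_relabeling_invariance(self, two_cpt_params, niclosamide):
        """The pooled objective does not depend on subject labels."""
        data = make_cohorts(two_cpt_params, niclosamide, ErrorModel(0.1, {}), seed=4)
        relabeled = PKDataset(
            doses=data.doses.assign(subject_id=lambda d: "x" + d.subject_id),
            observations=data.observations.assign(subject_id=lambda d: "x" + d.subject_id),
            lloq=data.lloq,
        )
        f1 = fit_single(data, seed=1)
        f2 = fit_single(relabeled, seed=1)
        assert f1.objective == pytest.approx(f2.objective, rel=1e-9)
        assert f1.params.CL == pytest.approx(f2.params.CL, rel=1e-6)


class TestFitCombined:
    def test_noiseless_fm_recovery(self):
        scenario = dataclasses.replace(valine_niclosamide_scenario(), error=NOISELESS)
        prodrug_dose, parent_only = simulate_conversion_study(scenario, seed=0)
        combined, _, _ = two_stage_fit(prodrug_dose, parent_only, seed=0)
        assert combined.params.Fm == pytest.approx(0.23, abs=1e-3)

    def test_null_conversion_recovered(self):
        """Data simulated with Fm = 0: the censored-record handling drives
        the estimate to (essentially) zero."""
        scenario = valine_niclosamide_scenario()
        scenario = dataclasses.replace(scenario, params=dataclasses.replace(scenario.params, Fm=0.0))
        prodrug_dose, parent_only = simulate_conversion_study(scenario, seed=11)
        combined, _, _ = two_stage_fit(prodrug_dose, parent_only, seed=11)
        assert combined.params.Fm <= 0.02

    def test_combined_fit_improves_on_seed(self):
        """Optimizer descent: the combined-fit objective is no worse than
        at the stage-one seed point."""
        scenario = valine_niclosamide_scenario()
        prodrug_dose, parent_only = simulate_conversion_study(scenario, seed=5)
        combined, stage_pd, stage_pa = two_stage_fit(prodrug_dose, parent_only, seed=5)
        seed_params = CombinedModelParams(
            prodrug=stage_pd.params, parent=stage_pa.params, Fm=0.3
        )
        obj_seed = combined_objective(
            seed_params,
            prodrug_dose.filter(analyte=ANALYTE_PRODRUG),
            prodrug_dose.filter(analyte=ANALYTE_PARENT),
            parent_only,
        )
        assert combined.objective <= obj_seed + 1e-9

    def test_missing_parent_arm_warns(self):
        scenario = valine_niclosamide_scenario()
        prodrug_dose, parent_only = simulate_conversion_study(scenario, seed=2)
        _, stage_pd, stage_pa = two_stage_fit(prodrug_dose, parent_only, seed=2)
        with pytest.warns(UserWarning, match="identifiable"):
            fit_combined(
                prodrug_dose.filter(analyte=ANALYTE_PRODRUG),
                prodrug_dose.filter(analyte=ANALYTE_PARENT),
                None,
                init_from=(stage_pd, stage_pa),
                seed=2,
            )

    def test_consistency_error_shrinks_with_noise(self):
        """Median |Fm error| over replicate studies shrinks as the residual
        error is reduced (estimator consistency, scaled-down check)."""
        base = valine_niclosamide_scenario()
        errors = {}
        for sd in (0.15, 0.02):
            scenario = dataclasses.replace(base, error=ErrorModel(proportional_sd=sd, iiv_sd={}))
            devs = []
            for seed in range(6):
                prodrug_dose, parent_only = simulate_conversion_study(scenario, seed=100 + seed)
                combined, _, _ = two_stage_fit(prodrug_dose, parent_only, seed=seed)
                devs.append(abs(combined.params.Fm - 0.23))
            errors[sd] = float(np.median(devs))
        assert errors[0.02] < errors[0.15]
        assert errors[0.02] < 0.01
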