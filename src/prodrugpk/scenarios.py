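"""Reference study scenarios for simulation-based validation.

The raw mouse concentration data behind the niclosamide valine-conjugate
case studies are not deposited, so the package validates its estimators by
parameter recovery: simulate a study at the reported typical estimates,
re-estimate, and compare.  This module collects those scenario
definitions — compounds, printed mg/kg doses, sampling schedules, typical
parameter values and variability — in one place.

Clearances and conversion fractions are the reported typical estimates
(e.g. niclosamide IV CL 0.08 L/h; conjugate CL 0.02–0.004 L/h; fraction
converted 23–39%).  Volumes, absorption rates and bioavailabilities were
never reported; the values here are fixed package defaults chosen to be
physiologically plausible for a 30 g mouse and broadly consistent with the
reported exposures (rationale in docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

from .compounds import ROUTE_IV, ROUTE_PO, Compound, default_registry
from .model import CombinedModelParams, DispositionParams
from .synth import IV_SCHEDULE, PO_SCHEDULE, ErrorModel, StudyDesign

#: Default study error model: 15% proportional residual CV and 20%
#: log-normal between-animal variability on CL and Vc.
STUDY_ERROR = ErrorModel(proportional_sd=0.15, iiv_sd={"CL": 0.2, "Vc": 0.2})


@dataclass(frozen=True)
class ConversionScenario:
    """A pro-drug/parent study pair: designs, compounds and true parameters."""

    name: str
    prodrug: Compound
    parent: Compound
    params: CombinedModelParams
    prodrug_iv: StudyDesign
    prodrug_po: StudyDesign
    parent_iv: StudyDesign
    parent_po: StudyDesign
    error: ErrorModel = STUDY_ERROR


@dataclass(frozen=True)
class SingleScenario:
    """A single-analyte dose group with known disposition."""

    name: str
    compound: Compound
    params: DispositionParams
    design: StudyDesign
    error: ErrorModel = STUDY_ERROR


def _designs(iv_dose: float, po_dose: float) -> tuple[StudyDesign, StudyDesign]:
    return (
        StudyDesign(route=ROUTE_IV, dose_mg_per_kg=iv_dose, schedule=IV_SCHEDULE),
        StudyDesign(route=ROUTE_PO, dose_mg_per_kg=po_dose, schedule=PO_SCHEDULE),
    )


def niclosamide_disposition() -> DispositionParams:
    """Typical niclosamide disposition (CL is the reported IV estimate)."""
    return DispositionParams(CL=0.08, Vc=0.15, Q=0.05, Vp=0.3, Ka=1.0, F=0.07)


def compound11_disposition() -> DispositionParams:
    return DispositionParams(CL=0.03, Vc=0.15, Q=0.04, Vp=0.3, Ka=0.8, F=0.06)


def valine_niclosamide_scenario() -> ConversionScenario:
    """Valine–niclosamide conversion study: Fm = 0.23, conjugate CL = 0.02 L/h."""
    reg = default_registry()
    prodrug_disp = DispositionParams(CL=0.02, Vc=0.008, Q=0.01, Vp=0.05, Ka=0.6, F=0.27)
    iv, po = _designs(2.8, 56.4)
    parent_iv, parent_po = _designs(2.0, 40.0)
    return ConversionScenario(
        name="valine_niclosamide",
        prodrug=reg["valine_niclosamide"],
        parent=reg["niclosamide"],
        params=CombinedModelParams(prodrug=prodrug_disp, parent=niclosamide_disposition(), Fm=0.23),
        prodrug_iv=iv,
        prodrug_po=po,
        parent_iv=parent_iv,
        parent_po=parent_po,
    )


def valine_compound11_scenario() -> ConversionScenario:
    """Valine–compound #11 conversion study: Fm = 0.39, conjugate CL = 0.004 L/h."""
    reg = default_registry()
    prodrug_disp = DispositionParams(CL=0.004, Vc=0.008, Q=0.002, Vp=0.01, Ka=0.5, F=0.005)
    iv, po = _designs(2.9, 56.18)
    parent_iv, parent_po = _designs(2.0, 40.0)
    return ConversionScenario(
        name="valine_compound_11",
        prodrug=reg["valine_compound_11"],
        parent=reg["compound_11"],
        params=CombinedModelParams(prodrug=prodrug_disp, parent=compound11_disposition(), Fm=0.39),
        prodrug_iv=iv,
        prodrug_po=po,
        parent_iv=parent_iv,
        parent_po=parent_po,
    )


def niclosamide_iv_scenario() -> SingleScenario:
    """Niclosamide 2 mg/kg IV group at the reported CL = 0.08 L/h."""
    reg = default_registry()
    return SingleScenario(
        name="niclosamide_iv",
        compound=reg["niclosamide"],
        params=niclosamide_disposition(),
        design=StudyDesign(route=ROUTE_IV, dose_mg_per_kg=2.0, schedule=IV_SCHEDULE),
    )


def valine_compound11_iv_scenario() -> SingleScenario:
    """Valine–compound #11 2.9 mg/kg IV group at the reported CL = 0.004 L/h."""
    reg = default_registry()
    return SingleScenario(
        name="valine_compound_11_iv",
        compound=reg["valine_compound_11"],
        params=DispositionParams(CL=0.004, Vc=0.008, Q=0.002, Vp=0.01),
        design=StudyDesign(route=ROUTE_IV, dose_mg_per_kg=2.9, schedule=IV_SCHEDULE),
    )


CONVERSION_SCENARIOS = {
    "valine_niclosamide": valine_niclosamide_scenario,
    "valine_compound_11": valine_compound11_scenario,
}

SINGLE_SCENARIOS = {
    "niclosamide_iv": niclosamide_iv_scenario,
    "valine_compound_11_iv": valine_compound11_iv_scenario,
}
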