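"""Compartment-model simulation against closed-form oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prodrugpk.compounds import ROUTE_IV, ROUTE_PO, Compound, DoseEvent, dose_umol
from prodrugpk.model import (
    CombinedModelParams,
    DispositionParams,
    combined_matrix,
    compartment_amounts_single,
    simulate_combined,
    simulate_single,
    single_analyte_matrix,
    solve_linear_amounts,
)


def iv_biexponential(params: DispositionParams, dose_umol_: float, t: np.ndarray) -> np.ndarray:
    """Textbook bi-exponential solution of the IV two-compartment model."""
    k10 = params.CL / params.Vc
    k12 = params.Q / params.Vc
    k21 = params.Q / params.Vp
    s = k10 + k12 + k21
    disc = np.sqrt(s**2 - 4 * k10 * k21)
    alpha, beta = (s + disc) / 2, (s - disc) / 2
    A = dose_umol_ * (alpha - k21) / (params.Vc * (alpha - beta))
    B = dose_umol_ * (k21 - beta) / (params.Vc * (alpha - beta))
    return A * np.exp(-alpha * t) + B * np.exp(-beta * t)


def bateman(params: DispositionParams, dose_umol_: float, t: np.ndarray) -> np.ndarray:
    """One-compartment first-order absorption closed form (Q = 0)."""
    k = params.CL / params.Vc
    ka = params.Ka
    return dose_umol_ * params.F * ka / (params.Vc * (ka - k)) * (np.exp(-k * t) - np.exp(-ka * t))


class TestSingleAnalyteOracles:
    def test_iv_one_compartment_exact(self, niclosamide):
        p = DispositionParams(CL=0.08, Vc=0.15, Q=0.0, Vp=1e-6)
        d = DoseEvent("m", 0.0, ROUTE_IV, 2.0, niclosamide)
        t = np.linspace(0.0, 12.0, 97)
        prof = simulate_single(p, d, t)
        exact = dose_umol(d) / p.Vc * np.exp(-p.CL / p.Vc * t)
        np.testing.assert_allclose(prof.conc, exact, rtol=1e-9)

    def test_po_bateman_oracle(self, niclosamide):
        p = DispositionParams(CL=0.08, Vc=0.15, Q=0.0, Vp=1e-6, Ka=1.2, F=0.4)
        d = DoseEvent("m", 0.0, ROUTE_PO, 40.0, niclosamide)
        t = np.linspace(0.01, 24.0, 200)
        prof = simulate_single(p, d, t)
        np.testing.assert_allclose(prof.conc, bateman(p, dose_umol(d), t), rtol=1e-6)

    def test_iv_two_compartment_biexponential_oracle(self, two_cpt_params, iv_dose):
        t = np.linspace(0.0, 24.0, 500)
        prof = simulate_single(two_cpt_params, iv_dose, t)
        np.testing.assert_allclose(
            prof.conc, iv_biexponential(two_cpt_params, dose_umol(iv_dose), t), rtol=1e-6
        )

    def test_degenerate_ka_falls_back(self, niclosamide):
        """Ka exactly equal to k10 makes the eigensystem defective; the
        matrix-exponential fallback must still give the right limit."""
        p = DispositionParams(CL=0.5, Vc=1.0, Q=0.0, Vp=1e-6, Ka=0.5, F=1.0)
        d = DoseEvent("m", 0.0, ROUTE_PO, 10.0, niclosamide)
        t = np.array([0.5, 1.0, 2.0, 4.0])
        prof = simulate_single(p, d, t)
        # limit of the Bateman equation as Ka -> k: C = D k t e^{-kt} / Vc
        exact = dose_umol(d) * 0.5 * t * np.exp(-0.5 * t)
        np.testing.assert_allclose(prof.conc, exact, rtol=1e-6)


class TestLinearity:
    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_dose_proportionality(self, scale):
        params = DispositionParams(CL=0.08, Vc=0.15, Q=0.05, Vp=0.3)
        compound = Compound(name="x", molar_mass=327.12)
        t = np.linspace(0.1, 12.0, 25)
        d1 = DoseEvent("m", 0.0, ROUTE_IV, 2.0, compound)
        d2 = DoseEvent("m", 0.0, ROUTE_IV, 2.0 * scale, compound)
        c1 = simulate_single(params, d1, t).conc
        c2 = simulate_single(params, d2, t).conc
        np.testing.assert_allclose(c2, scale * c1, rtol=1e-9)

    def test_superposition_of_two_doses(self, two_cpt_params, niclosamide):
        t = np.linspace(0.0, 24.0, 100)
        d0 = DoseEvent("m", 0.0, ROUTE_IV, 2.0, niclosamide)
        d4 = DoseEvent("m", 4.0, ROUTE_IV, 2.0, niclosamide)
        both = simulate_single(two_cpt_params, d0, t).conc + simulate_single(two_cpt_params, d4, t).conc
        # response before the second dose equals the single-dose response
        single = simulate_single(two_cpt_params, d0, t).conc
        np.testing.assert_allclose(both[t < 4.0], single[t < 4.0], rtol=1e-12)
        # after it, strictly above the single-dose curve
        assert np.all(both[t >= 4.0] >= single[t >= 4.0])


class TestConservation:
    @pytest.mark.parametrize("route,dose_mgkg", [(ROUTE_IV, 2.0), (ROUTE_PO, 40.0)])
    def test_mass_balance(self, route, dose_mgkg, two_cpt_params, niclosamide):
        """Compartment amounts plus cumulative elimination equal the
        (absorbed) dose at every time, to integrator accuracy."""
        d = DoseEvent("m", 0.0, route, dose_mgkg, niclosamide)
        oral = route == ROUTE_PO
        A = single_analyte_matrix(two_cpt_params, oral)
        n = A.shape[0]
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = A
        aug[n, :n] = -A.sum(axis=0)  # all outflow collects in a sink state
        x0 = np.zeros(n + 1)
        amount = dose_umol(d) * (two_cpt_params.F if oral else 1.0)
        x0[0 if oral else 0] = amount
        t = np.linspace(0.0, 48.0, 200)
        states = solve_linear_amounts(aug, x0, t)
        np.testing.assert_allclose(states.sum(axis=1), amount, rtol=1e-8)

    def test_nonnegative_concentrations(self, combined_params, registry):
        d = DoseEvent("m", 0.0, ROUTE_PO, 56.4, registry["valine_niclosamide"])
        t = np.linspace(0.0, 48.0, 300)
        pro, par = simulate_combined(combined_params, d, t)
        assert np.all(pro.conc >= 0) and np.all(par.conc >= 0)


class TestCombinedModel:
    def test_fm_zero_gives_no_parent(self, combined_params, registry):
        params = CombinedModelParams(
            prodrug=combined_params.prodrug, parent=combined_params.parent, Fm=0.0
        )
        d = DoseEvent("m", 0.0, ROUTE_IV, 2.8, registry["valine_niclosamide"])
        t = np.linspace(0.0, 24.0, 100)
        _, parent = simulate_combined(params, d, t)
        assert np.all(parent.conc == 0.0)

    def test_fm_one_conserves_dose(self, combined_params, registry):
        """With Fm = 1 every eliminated pro-drug molecule becomes parent:
        parent AUC × parent CL equals the full pro-drug dose."""
        params = CombinedModelParams(
            prodrug=combined_params.prodrug, parent=combined_params.parent, Fm=1.0
        )
        d = DoseEvent("m", 0.0, ROUTE_IV, 2.8, registry["valine_niclosamide"])
        t = np.linspace(0.0, 2000.0, 40001)
        _, parent = simulate_combined(params, d, t)
        formed = np.trapezoid(parent.conc, t) * params.parent.CL
        assert formed == pytest.approx(dose_umol(d), rel=1e-3)

    def test_metabolite_auc_identity(self, registry):
        """AUC of the formed parent equals Fm × Dose / CLp (linear-systems
        identity), checked by quadrature on a dense grid."""
        prodrug = DispositionParams(CL=0.1, Vc=0.05, Q=0.0, Vp=1e-6)
        parent = DispositionParams(CL=0.02, Vc=0.1, Q=0.0, Vp=1e-6)
        params = CombinedModelParams(prodrug=prodrug, parent=parent, Fm=0.5)
        compound = Compound(name="pro", molar_mass=461.24, role="prodrug", parent_name="niclosamide")
        # 1 µmol dose: mg/kg chosen so dose_umol == 1
        mgkg = 461.24 / (0.030 * 1000)
        d = DoseEvent("m", 0.0, ROUTE_IV, mgkg, compound)
        assert dose_umol(d) == pytest.approx(1.0, rel=1e-12)
        # >= 20 parent half-lives: t_half = ln2/(CLp/Vc) = 3.47 h
        t = np.linspace(0.0, 120.0, 60001)
        _, par = simulate_combined(params, d, t)
        auc = np.trapezoid(par.conc, t)
        assert auc == pytest.approx(0.5 * 1.0 / 0.02, rel=0.02)
        assert auc == pytest.approx(25.0, rel=0.02)

    def test_parent_dose_bypasses_prodrug(self, combined_params, registry):
        d = DoseEvent("m", 0.0, ROUTE_IV, 2.0, registry["niclosamide"])
        t = np.linspace(0.0, 12.0, 50)
        pro, par = simulate_combined(combined_params, d, t)
        assert np.all(pro.conc == 0.0)
        direct = simulate_single(combined_params.parent, d, t)
        np.testing.assert_allclose(par.conc, direct.conc, rtol=1e-12)


class TestValidation:
    def test_negative_times_rejected(self, two_cpt_params, iv_dose):
        with pytest.raises(ValueError):
            simulate_single(two_cpt_params, iv_dose, np.array([-1.0, 0.0, 1.0]))

    def test_unsorted_times_rejected(self, two_cpt_params, iv_dose):
        with pytest.raises(ValueError):
            simulate_single(two_cpt_params, iv_dose, np.array([1.0, 0.5]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DispositionParams(CL=-0.1, Vc=0.1, Q=0.0, Vp=0.1)
        with pytest.raises(ValueError):
            DispositionParams(CL=0.1, Vc=0.1, Q=0.0, Vp=0.1, F=1.5)

    def test_fm_out_of_range_rejected(self, two_cpt_params):
        with pytest.raises(ValueError):
            CombinedModelParams(prodrug=two_cpt_params, parent=two_cpt_params, Fm=1.2)
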