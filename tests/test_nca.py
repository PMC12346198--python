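"""Non-compartmental analysis: AUC, terminal slope, clearance, bioavailability."""

import math

import numpy as np
import pytest

from prodrugpk.compounds import ROUTE_IV, ROUTE_PO, DoseEvent, dose_umol
from prodrugpk.model import DispositionParams, simulate_single
from prodrugpk.nca import (
    NCAResult,
    apply_blq_policy,
    auc_trapezoid,
    bioavailability,
    fold_change,
    nca_profile,
    summarize_group,
)


class TestAucTrapezoid:
    def test_hand_examples(self):
        assert auc_trapezoid([0, 1, 2], [0, 2, 1]) == pytest.approx(2.5)
        assert auc_trapezoid([0, 4], [3, 3]) == pytest.approx(12.0)

    def test_exponential_oracle(self):
        t = np.linspace(0, 10, 2000)
        c0, k = 5.0, 0.8
        area = auc_trapezoid(t, c0 * np.exp(-k * t))
        assert area == pytest.approx(c0 / k * (1 - math.exp(-k * 10)), rel=1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            auc_trapezoid([1.0], [2.0])

    def test_monotone_in_added_observations(self):
        t = np.array([0.0, 1.0, 2.0])
        c = np.array([1.0, 0.5, 0.25])
        base = auc_trapezoid(t, c)
        extended = auc_trapezoid(np.append(t, 3.0), np.append(c, 0.1))
        assert extended >= base


class TestLambdaZAndClearance:
    def test_iv_clearance_recovery_dense(self, niclosamide):
        """Noiseless two-compartment profile sampled densely to 10 terminal
        half-lives: NCA clearance within 2% of the model CL."""
        p = DispositionParams(CL=0.08, Vc=0.15, Q=0.05, Vp=0.3)
        d = DoseEvent("m", 0.0, ROUTE_IV, 2.0, niclosamide)
        # terminal half-life ~7.3 h; log-spaced sampling as in PK practice
        t = np.geomspace(0.05, 73.0, 64)
        res = nca_profile(simulate_single(p, d, t), dose=d)
        assert res.cl == pytest.approx(0.08, rel=0.02)
        assert res.lambda_z is not None and res.lambda_z > 0
        assert res.auc_inf >= res.auc_all >= 0

    def test_study_schedule_clearance(self, niclosamide):
        """The sparse 7-point study schedule still recovers CL within ~10%
        on a noiseless profile."""
        p = DispositionParams(CL=0.08, Vc=0.15, Q=0.05, Vp=0.3)
        d = DoseEvent("m", 0.0, ROUTE_IV, 2.0, niclosamide)
        t = np.array([0.083, 0.25, 0.5, 1.0, 2.0, 6.0, 12.0])
        res = nca_profile(simulate_single(p, d, t), dose=d)
        assert res.cl == pytest.approx(0.08, rel=0.10)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            nca_profile((np.array([1.0]), np.array([2.0])))

    def test_monotone_increasing_profile_flagged(self):
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        c = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = nca_profile((t, c))
        assert res.lambda_z is None
        assert res.auc_inf is None
        assert any("lambda_z" in f for f in res.flags)

    def test_cmax_tmax(self):
        t = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
        c = np.array([1.0, 3.0, 2.5, 1.0, 0.4])
        res = nca_profile((t, c))
        assert res.cmax == 3.0 and res.tmax == 0.5


class TestBlqPolicy:
    def test_leading_zeroed_trailing_dropped(self):
        t = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
        c = np.array([np.nan, 1.0, 2.0, 1.0, np.nan, np.nan])
        blq = np.array([True, False, False, False, True, True])
        t2, c2 = apply_blq_policy(t, c, blq)
        np.testing.assert_array_equal(t2, [0.25, 0.5, 1.0, 2.0])
        np.testing.assert_array_equal(c2, [0.0, 1.0, 2.0, 1.0])

    def test_all_blq_errors(self):
        with pytest.raises(ValueError):
            apply_blq_policy([1.0, 2.0], [np.nan, np.nan], [True, True])


class TestBioavailabilityAndFold:
    def test_arithmetic(self):
        po = NCAResult(cmax=1, tmax=1, auc_all=1.0, auc_inf=1.0)
        iv = NCAResult(cmax=4, tmax=0.1, auc_all=4.0, auc_inf=4.0)
        assert bioavailability(po, 1.0, iv, 1.0) == pytest.approx(0.25)
        assert bioavailability(po, 2.0, iv, 2.0) == pytest.approx(0.25)
        same = bioavailability(iv, 1.0, iv, 1.0)
        assert same == pytest.approx(1.0)

    def test_simulated_f_recovery(self, niclosamide):
        """PO and IV profiles simulated with true F = 0.3 and shared
        disposition recover F within 5% from dose-normalized AUCs."""
        p = DispositionParams(CL=0.08, Vc=0.15, Q=0.05, Vp=0.3, Ka=1.0, F=0.3)
        iv_d = DoseEvent("m", 0.0, ROUTE_IV, 2.0, niclosamide)
        po_d = DoseEvent("m", 0.0, ROUTE_PO, 40.0, niclosamide)
        t = np.linspace(0.05, 96.0, 400)
        iv_res = nca_profile(simulate_single(p, iv_d, t), dose=iv_d)
        po_res = nca_profile(simulate_single(p, po_d, t), dose=po_d)
        f = bioavailability(po_res, dose_umol(po_d), iv_res, dose_umol(iv_d))
        assert f == pytest.approx(0.3, rel=0.05)

    def test_fold_change(self):
        assert fold_change(48.57, 3.25) == pytest.approx(14.94, abs=0.01)
        assert fold_change(5.0, 5.0) == 1.0
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestGroupSummary:
    def test_geometric_mean(self):
        results = [
            NCAResult(cmax=2.0, tmax=1.0, auc_all=10.0, cl=0.08),
            NCAResult(cmax=8.0, tmax=1.0, auc_all=10.0, cl=0.08),
        ]
        table = summarize_group(results)
        assert table.loc["cmax", "geomean"] == pytest.approx(4.0)
        assert table.loc["cl", "gcv"] == pytest.approx(0.0)

    def test_single_value_cv_undefined(self):
        table = summarize_group([NCAResult(cmax=2.0, tmax=1.0, auc_all=5.0)])
        assert table.loc["cmax", "geomean"] == pytest.approx(2.0)
        assert math.isnan(table.loc["cmax", "gcv"])

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            summarize_group([])
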