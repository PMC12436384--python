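"""Closed-form two-compartment solutions against an independent ODE oracle
and their analytic invariants (superposition, mass balance, washout)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import dexpop as dp
from dexpop.structural import disposition_macro
from oracles import ode_conc

TYPICAL_PATIENT = dp.IndividualParams(
    cl=35.3, vc=21.5, q=116.0, vp=86.5, ka=0.523, f1=0.653, alag=0.0592
)
GRID = np.array([0.05, 0.1, 0.25, 0.26, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 24.0])


def scaled(p: dp.IndividualParams, bw: float, ref: float = 60.0):
    w = bw / ref
    return dp.IndividualParams(
        cl=p.cl * w**0.75, vc=p.vc * w, q=p.q * w**0.75, vp=p.vp * w,
        ka=p.ka, f1=p.f1, alag=p.alag,
    )


class TestAgainstOdeOracle:
    def test_iv_infusion_matches_ode(self):
        d = dp.DoseEvent(0.0, 40.0, "iv_infusion", 0.25)
        closed = dp.conc_iv_infusion(TYPICAL_PATIENT, d, GRID)
        numeric = ode_conc(TYPICAL_PATIENT, [d], GRID)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_firstorder_matches_ode(self):
        d = dp.DoseEvent(0.0, 100.0, "intranasal")
        closed = dp.conc_firstorder(TYPICAL_PATIENT, d, GRID)
        numeric = ode_conc(TYPICAL_PATIENT, [d], GRID)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_staggered_multidose_matches_ode(self):
        regimen = [
            dp.DoseEvent(0.0, 100.0, "intranasal"),
            dp.DoseEvent(1.5, 20.0, "intranasal"),
            dp.DoseEvent(3.0, 40.0, "iv_infusion", 0.25),
        ]
        closed = dp.conc_profile(TYPICAL_PATIENT, regimen, GRID)
        numeric = ode_conc(TYPICAL_PATIENT, regimen, GRID)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6, atol=1e-9)

    def test_degenerate_ka_equal_macro_rate(self):
        lam1, lam2, _, _ = disposition_macro(TYPICAL_PATIENT)
        p = dp.IndividualParams(
            cl=TYPICAL_PATIENT.cl, vc=TYPICAL_PATIENT.vc, q=TYPICAL_PATIENT.q,
            vp=TYPICAL_PATIENT.vp, ka=lam2, f1=0.653, alag=0.0,
        )
        d = dp.DoseEvent(0.0, 100.0, "intranasal")
        closed = dp.conc_firstorder(p, d, GRID)
        assert np.all(np.isfinite(closed))
        numeric = ode_conc(p, [d], GRID)
        np.testing.assert_allclose(closed, numeric, rtol=1e-5)


class TestMassBalance:
    @pytest.mark.parametrize("route,f_eff", [("intranasal", 0.653), ("iv_infusion", 1.0)])
    def test_auc_times_cl_equals_f_dose(self, route, f_eff):
        dose = 100.0
        d = (dp.DoseEvent(0.0, dose, route, 0.25) if route == "iv_infusion"
             else dp.DoseEvent(0.0, dose, route))
        fn = (dp.conc_iv_infusion if route == "iv_infusion"
              else dp.conc_firstorder)
        auc, _ = quad(lambda t: fn(TYPICAL_PATIENT, d, t), 0.0, np.inf,
                      limit=400)
        expected = 1000.0 * f_eff * dose / TYPICAL_PATIENT.cl
        assert auc == pytest.approx(expected, rel=1e-6)


class TestBoundaryBehavior:
    def test_zero_dose_gives_zero_everywhere(self):
        d = dp.DoseEvent(0.0, 0.0, "intranasal")
        assert np.all(dp.conc_firstorder(TYPICAL_PATIENT, d, GRID) == 0.0)

    def test_zero_before_dose_and_lag(self):
        d = dp.DoseEvent(1.0, 100.0, "intranasal")
        t = np.array([0.0, 0.5, 1.0, 1.0 + TYPICAL_PATIENT.alag])
        assert np.all(dp.conc_firstorder(TYPICAL_PATIENT, d, t) == 0.0)

    def test_washout(self):
        d = dp.DoseEvent(0.0, 100.0, "intranasal")
        assert dp.conc_firstorder(TYPICAL_PATIENT, d, 500.0) < 1e-10

    def test_continuous_at_infusion_end(self):
        d = dp.DoseEvent(0.0, 40.0, "iv_infusion", 0.25)
        eps = 1e-9
        lo = dp.conc_iv_infusion(TYPICAL_PATIENT, d, 0.25 - eps)
        hi = dp.conc_iv_infusion(TYPICAL_PATIENT, d, 0.25 + eps)
        assert hi == pytest.approx(lo, rel=1e-6)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            dp.IndividualParams(cl=-1.0, vc=20.0, q=100.0, vp=80.0)
        with pytest.raises(ValueError):
            dp.IndividualParams(cl=30.0, vc=20.0, q=100.0, vp=80.0, f1=1.2)
        with pytest.raises(ValueError):
            dp.DoseEvent(0.0, 40.0, "iv_infusion", 0.0)


@st.composite
def params_strategy(draw):
    return dp.IndividualParams(
        cl=draw(st.floats(10.0, 80.0)),
        vc=draw(st.floats(10.0, 60.0)),
        q=draw(st.floats(30.0, 200.0)),
        vp=draw(st.floats(30.0, 200.0)),
        ka=draw(st.floats(0.2, 4.0)),
        f1=draw(st.floats(0.3, 1.0)),
        alag=draw(st.floats(0.0, 0.15)),
    )


class TestLinearity:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(params_strategy())
    def test_superposition_and_nonnegativity(self, p):
        regimen = [
            dp.DoseEvent(0.0, 100.0, "intranasal"),
            dp.DoseEvent(0.0, 20.0, "intranasal"),
        ]
        total = dp.conc_profile(p, regimen, GRID)
        parts = sum(
            np.asarray(dp.conc_firstorder(p, d, GRID)) for d in regimen
        )
        np.testing.assert_allclose(total, parts, rtol=1e-12, atol=1e-12)
        assert np.all(total >= 0.0)

    def test_split_dose_scales_linearly(self):
        both = dp.conc_profile(
            TYPICAL_PATIENT,
            [dp.DoseEvent(0.0, 100.0, "intranasal"),
             dp.DoseEvent(0.0, 20.0, "intranasal")],
            GRID,
        )
        single = dp.conc_profile(
            TYPICAL_PATIENT, [dp.DoseEvent(0.0, 100.0, "intranasal")], GRID
        )
        np.testing.assert_allclose(both, 1.2 * single, rtol=1e-12)

    def test_single_dose_profile_equals_single_dose_operation(self):
        d = dp.DoseEvent(0.0, 150.0, "intranasal")
        np.testing.assert_array_equal(
            dp.conc_profile(TYPICAL_PATIENT, [d], GRID),
            np.asarray(dp.conc_firstorder(TYPICAL_PATIENT, d, GRID)),
        )

    def test_empty_regimen_gives_zeros(self):
        assert np.all(dp.conc_profile(TYPICAL_PATIENT, [], GRID) == 0.0)


class TestCmaxWindow:
    REGIMEN = [dp.DoseEvent(0.0, 100.0, "intranasal")]

    def test_matches_brute_force_grid(self):
        cmax, tmax = dp.cmax_in_window(TYPICAL_PATIENT, self.REGIMEN, (0.0, 24.0))
        t = np.linspace(0.0, 24.0, 100_001)
        brute = dp.conc_profile(TYPICAL_PATIENT, self.REGIMEN, t)
        i = int(np.argmax(brute))
        assert cmax == pytest.approx(brute[i], rel=1e-7)
        assert tmax == pytest.approx(t[i], abs=2e-3)

    def test_window_before_lag_gives_zero(self):
        cmax, tmax = dp.cmax_in_window(
            TYPICAL_PATIENT, self.REGIMEN, (0.0, TYPICAL_PATIENT.alag / 2.0)
        )
        assert cmax == 0.0 and tmax == 0.0

    def test_restricted_window_not_larger_than_global(self):
        c45, _ = dp.cmax_in_window(TYPICAL_PATIENT, self.REGIMEN, (0.0, 0.75))
        cg, _ = dp.cmax_in_window(TYPICAL_PATIENT, self.REGIMEN, (0.0, 24.0))
        assert c45 <= cg

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            dp.cmax_in_window(TYPICAL_PATIENT, self.REGIMEN, (2.0, 1.0))
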