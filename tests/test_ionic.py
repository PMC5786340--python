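"""Deterministic whole-cell model: gating algebra, integration and pacing."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from coopgate.ionic import (IonicParams, IonicState, Y_CI, Y_CJ, Y_CS, Y_D,
                            Y_F, Y_FCA, Y_V, NY, gamma_d, integrate,
                            ionic_rhs, pace, voltage_clamp)


@pytest.fixture
def params():
    return IonicParams()


class TestGammaD:
    def test_disabled_coupling(self, params):
        assert gamma_d(0.5, 1.0, params.with_(w=0.0)) == 1.0

    def test_double_midpoint_quarter_weight(self):
        """Both logistic factors are 1/2 at their midpoints, so
        gamma_d = 1 + gain*w/4; checked with the printed-scale gain."""
        p = IonicParams().with_(w=2.0, coup_gain=0.01, po_x=0.3, cs_x=1.0)
        assert gamma_d(0.3, 1.0, p) == pytest.approx(1.0 + 0.01 * 2.0 / 4.0)

    def test_saturation(self, params):
        p = params.with_(w=1.0)
        assert gamma_d(1.0, 100.0, p) == pytest.approx(
            1.0 + p.coup_gain * p.w, rel=1e-6)

    def test_monotone(self, params):
        p = params.with_(w=1.0)
        gs = [gamma_d(x, 1.0, p) for x in np.linspace(0, 1, 11)]
        assert np.all(np.diff(gs) >= 0)
        gs = [gamma_d(0.2, c, p) for c in np.linspace(0, 5, 11)]
        assert np.all(np.diff(gs) >= 0)

    def test_domain(self, params):
        with pytest.raises(ValueError):
            gamma_d(1.5, 1.0, params)
        with pytest.raises(ValueError):
            gamma_d(0.5, -1.0, params)


class TestRhs:
    def test_d_gate_steady_state_at_fixed_voltage(self, params):
        """With w = 0 and the d-gate at its steady state d_inf(V), the
        d-derivative vanishes."""
        st = IonicState.resting()
        V = -20.0
        st.y[Y_V] = V
        st.y[Y_D] = 1.0 / (1.0 + math.exp(-(V + 5.0) / 6.24))
        dy = ionic_rhs(st, 0.0, params.with_(w=0.0))
        assert dy[Y_D] == pytest.approx(0.0, abs=1e-12)

    def test_d_activation_midpoint(self):
        assert 1.0 / (1.0 + math.exp(-(-5.0 + 5.0) / 6.24)) == 0.5

    def test_coupled_d_fixed_point_matches_root_finder(self, params):
        """With gamma_d active, the d-gate fixed point at clamped
        (V, c_s, f, f_Ca) solves alpha*gamma_d(d)*(1-d) = beta*d; the RHS
        zero matches an independent scalar root-finder."""
        p = params.with_(w=1.0)
        V, cs, f, fca = 0.0, 1.5, 0.8, 0.6
        d_inf = 1.0 / (1.0 + math.exp(-(V + 5.0) / 6.24))

        def resid(d):
            st = IonicState.resting()
            st.y[Y_V], st.y[Y_CS] = V, cs
            st.y[Y_D], st.y[Y_F], st.y[Y_FCA] = d, f, fca
            return ionic_rhs(st, 0.0, p)[Y_D]

        d_star = brentq(resid, 1e-6, 1.0 - 1e-9, xtol=1e-12)
        g = gamma_d(d_star * f * fca, cs, p)
        expect = g * d_inf / (g * d_inf + (1.0 - d_inf))
        assert d_star == pytest.approx(expect, rel=1e-8)

    def test_w_zero_reduces_to_base_model(self, params):
        """The RHS with w = 0 is identical to the base model regardless of
        the coupling sensitivities (gamma_d == 1 exactly)."""
        st = IonicState.resting()
        st.y[Y_V], st.y[Y_CS], st.y[Y_D] = -10.0, 2.0, 0.4
        d0 = ionic_rhs(st, 0.0, params.with_(w=0.0, po_x=0.0, cs_x=0.0))
        d1 = ionic_rhs(st, 0.0, params.with_(w=0.0, po_x=0.9, cs_x=9.0))
        assert np.array_equal(d0, d1)


class TestIntegrate:
    def test_rest_is_quiescent(self, params):
        """Without stimulus the membrane stays within 1 mV of rest for
        10 seconds."""
        st = IonicState.resting()
        t, Y, _ = integrate(st, params, 10_000.0, dt=0.01, stride=2000)
        assert np.abs(Y[:, Y_V] - Y[0, Y_V]).max() < 1.0

    def test_gates_and_concentrations_stay_in_domain(self, params):
        ser, st, _ = pace(params, 300.0, 5, dt=0.01)
        y = st.y
        for i in range(1, 11):
            assert 0.0 <= y[i] <= 1.0
        assert y[Y_CS] >= 0.0 and y[Y_CI] >= 0.0 and y[Y_CJ] >= 0.0

    def test_apd_converges_in_dt(self, params):
        """Halving the time step changes the steady-pacing APD by less
        than 0.1 ms (first-order scheme: checked at the fine end of the
        step-size range; the dt = 0.01 default carries a ~0.3 ms bias that
        is uniform across compared conditions)."""
        a1 = pace(params, 400.0, 12, dt=0.0025)[0].apd[-1]
        a2 = pace(params, 400.0, 12, dt=0.00125)[0].apd[-1]
        assert abs(a1 - a2) < 0.1

    def test_zero_conductances_freeze_voltage(self, params):
        p = params.with_(g_na=0, g_k1=0, g_kr=0, g_ks=0, g_to=0, g_kp=0,
                         g_ca=0, v_ncx=0)
        st = IonicState.resting()
        t, Y, _ = integrate(st, p, 500.0, dt=0.01, stride=100)
        assert np.abs(Y[:, Y_V] - Y[0, Y_V]).max() < 1e-9

    def test_blowup_detected(self, params):
        p = params.with_(g_na=1e5)
        st = IonicState.resting()
        istim = np.zeros(50_000)
        istim[:100] = -80.0
        with pytest.raises(FloatingPointError):
            integrate(st, p, 500.0, dt=0.01, istim=istim)


class TestPace:
    def test_reference_parameters_are_stable(self, params):
        """tau_f = 45 ms, u = 3, w = 0 pace to a steady state without
        alternans."""
        ser, st, steady = pace(params.with_(tau_f=45.0, u=3.0, w=0.0),
                               400.0, 60, dt=0.01)
        assert steady
        assert np.abs(np.diff(ser.apd[-8:])).max() < 1.0

    def test_step_clamp_amplification_with_coupling(self, params):
        """-80 -> +20 mV clamp: w = 1 increases peak I_CaL about 1.5-fold
        over w = 0."""
        _, i0, _ = voltage_clamp(params.with_(w=0.0), dt=0.01)
        _, i1, _ = voltage_clamp(params.with_(w=1.0), dt=0.01)
        ratio = i1.min() / i0.min()
        assert 1.35 <= ratio <= 1.65

    def test_apd_increases_with_coupling_strength(self, params):
        apds = []
        for w in (0.0, 0.3, 1.0):
            ser, _, _ = pace(params.with_(w=w), 400.0, 40, dt=0.01)
            apds.append(ser.apd[-2:].mean())
        assert apds[0] < apds[1] < apds[2]

    def test_flux_current_conversion_consistency(self, params):
        """The Ca charge carried by I_CaL over a clamp step equals
        -2 alpha times the time-integral of the Ca flux reconstructed
        independently from the recorded states."""
        t, ical, Y = voltage_clamp(params, v_test=0.0, dt=0.01, step_ms=100.0)
        # independent reconstruction of J_Ca from the recorded gates/cs
        rtf, cao = params.rt_f, params.ca_o
        V = 0.0
        cs_mm = Y[:, Y_CS] * 1e-3
        z = V / rtf
        ica_hat = 2.0 * (cs_mm - 0.34 * cao)  # V = 0 limit
        j_ca = -params.g_ca * Y[:, Y_D] * Y[:, Y_F] * Y[:, Y_FCA] * ica_hat
        expect = -2.0 * params.alpha_conv * j_ca
        # compare the time-integrals (recorded ical vs reconstruction)
        q1 = np.trapezoid(ical, t)
        q2 = np.trapezoid(expect, t)
        assert q1 == pytest.approx(q2, rel=2e-2)
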