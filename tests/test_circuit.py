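"""Coefficient transforms, characteristic time constants and the closed-form
step response of the two-compartment circuit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tubcap as tc


def brute_force_rates(coeffs, n=2_000_001):
    """Independent oracle: scan rate space for the sign changes of the
    characteristic polynomial and refine by bisection."""
    S = coeffs.k_t / coeffs.tau_t + coeffs.k_st / coeffs.tau_s
    P = coeffs.denom / (coeffs.tau_s * coeffs.tau_t)
    poly = lambda lam: lam * lam - S * lam + P
    grid = np.linspace(0.0, 1.2 * S, n)
    vals = poly(grid)
    roots = []
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        lo, hi = grid[i], grid[i + 1]
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if poly(lo) * poly(mid) <= 0:
                hi = mid
            else:
                lo = mid
        roots.append(0.5 * (lo + hi))
    assert len(roots) == 2
    return sorted(roots)


class TestDerivedCoeffs:
    def test_verification_circuit_values(self, verif_circuit):
        c = tc.derive_coeffs(verif_circuit)
        assert c.tau_t == pytest.approx(690.0)
        assert c.tau_s == pytest.approx(925.0)
        assert c.k_at == pytest.approx(12.5 / 15.0)
        assert c.k_t == pytest.approx(1 + 15.0 / 241.0)
        assert c.k_st == pytest.approx(1 + 12.5 / 150.0 + 12.5 / 15.0)
        assert c.k_Ut == pytest.approx(-160.0 * 15.0 / 241.0)
        assert c.k_Us == pytest.approx(-160.0 * 12.5 / 150.0)
        assert not c.degenerate

    def test_small_R_t_limit_flagged_degenerate(self, verif_circuit):
        # R_t -> 0: tau_t -> 0, k_t -> 1, k_at -> inf
        tiny = verif_circuit.replace(R_t=1e-12)
        c = tc.derive_coeffs(tiny)
        assert c.tau_t == pytest.approx(0.0, abs=1e-9)
        assert c.k_t == pytest.approx(1.0)
        assert c.k_at > 1e10

    @pytest.mark.parametrize("element", ["R_a", "R_t", "R_ms", "R_mt", "C_s", "C_t"])
    def test_nonpositive_element_rejected_by_name(self, verif_circuit, element):
        with pytest.raises(ValueError, match=element):
            verif_circuit.replace(**{element: 0.0})
        with pytest.raises(ValueError, match=element):
            verif_circuit.replace(**{element: -1.0})

    def test_nonfinite_reversal_voltage_rejected(self, verif_circuit):
        with pytest.raises(ValueError, match="U_ms"):
            verif_circuit.replace(U_ms=math.nan)


class TestCharacteristicTimeConstants:
    def test_verification_circuit_versus_brute_force_scan(self, verif_circuit):
        c = tc.derive_coeffs(verif_circuit)
        tau_1, tau_2 = tc.characteristic_time_constants(c)
        r_slow, r_fast = brute_force_rates(c)
        assert tau_1 == pytest.approx(1.0 / r_slow, rel=1e-8)
        assert tau_2 == pytest.approx(1.0 / r_fast, rel=1e-8)
        # frozen values from the oracle
        assert tau_1 == pytest.approx(1581.02, rel=1e-4)
        assert tau_2 == pytest.approx(335.678, rel=1e-4)
        assert tau_1 >= tau_2 > 0

    @given(
        R_a=st.floats(5.0, 25.0), R_t=st.floats(5.0, 100.0),
        R_ms=st.floats(50.0, 500.0), R_mt=st.floats(100.0, 2000.0),
        C_s=st.floats(20.0, 200.0), C_t=st.floats(5.0, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_rate_sum_and_product_identities(self, R_a, R_t, R_ms, R_mt, C_s, C_t):
        """The returned pair satisfies the sum- and product-of-rates
        identities of the characteristic equation to 1e-10 relative."""
        c = tc.derive_coeffs(tc.CircuitParams(R_a, R_t, R_ms, R_mt, C_s, C_t))
        tau_1, tau_2 = tc.characteristic_time_constants(c)
        lhs_sum = 1.0 / tau_1 + 1.0 / tau_2
        rhs_sum = c.k_t / c.tau_t + c.k_st / c.tau_s
        assert lhs_sum == pytest.approx(rhs_sum, rel=1e-10)
        lhs_prod = 1.0 / (tau_1 * tau_2)
        rhs_prod = c.denom / (c.tau_s * c.tau_t)
        assert lhs_prod == pytest.approx(rhs_prod, rel=1e-10)


class TestAnalyticStepResponse:
    def test_zero_amplitude_step_is_constant(self, verif_circuit):
        proto = tc.StepProtocol(U_1=-80, U_2=-80, tau_p=0.0)
        resp = tc.analytic_step_response(verif_circuit, proto)
        assert resp.c_1 == pytest.approx(0.0, abs=1e-12)
        assert resp.c_2 == pytest.approx(0.0, abs=1e-12)
        assert resp.J_inf_1 == pytest.approx(resp.J_inf_2)
        assert np.allclose(resp.J, resp.J_inf_1, atol=1e-12)

    def test_instantaneous_jump_identity(self, verif_circuit, ideal_protocol):
        # J_1 + J_2 + J_inf_2 - J_inf_1 = (U_2 - U_1)/R_a = 0.4 nA
        r = tc.analytic_step_response(verif_circuit, ideal_protocol)
        jump = r.J_1 + r.J_2 + r.J_inf_2 - r.J_inf_1
        assert jump == pytest.approx(5.0 / 12.5, rel=1e-12)

    def test_steady_state_difference_identity(self, verif_circuit, ideal_protocol):
        r = tc.analytic_step_response(verif_circuit, ideal_protocol)
        c = tc.derive_coeffs(verif_circuit)
        expected = (
            (ideal_protocol.U_2 - ideal_protocol.U_1)
            * (c.denom - c.k_t) / (verif_circuit.R_a * c.denom))
        assert r.J_inf_2 - r.J_inf_1 == pytest.approx(expected, rel=1e-12)

    def test_matches_ode_integration(self, verif_circuit, ideal_protocol):
        resp = tc.analytic_step_response(verif_circuit, ideal_protocol, dt=0.02)
        trace = tc.simulate_step(verif_circuit, ideal_protocol, dt=0.02)
        ode = trace.window(0.0)
        assert np.abs(ode.J - resp.J).max() < 1e-6

    def test_tubular_steady_state_matches_long_time_ode(self, verif_circuit):
        """The re-derived constant term of the tubular voltage equals the
        ODE solution after many time constants."""
        proto = tc.StepProtocol(U_1=-80, U_2=-75, t_step=40.0, tau_p=0.0)
        trace = tc.simulate_step(verif_circuit, proto, dt=0.05)
        c = tc.derive_coeffs(verif_circuit)
        _, Ut_inf = tc.steady_state(c, -75.0)
        assert trace.U_t[-1] == pytest.approx(Ut_inf, rel=1e-9)

    def test_requires_ideal_step(self, verif_circuit, step_protocol):
        with pytest.raises(ValueError, match="tau_p"):
            tc.analytic_step_response(verif_circuit, step_protocol)

    def test_small_R_t_collapses_to_mono_exponential(self, verif_circuit):
        """Towards the physiological regime the fast component carries a
        vanishing share of the transferred charge."""
        proto = tc.StepProtocol(tau_p=0.0)
        resp = tc.analytic_step_response(verif_circuit.replace(R_t=0.001), proto)
        charge_slow = abs(resp.J_1 * resp.tau_1)
        charge_fast = abs(resp.J_2 * resp.tau_2)
        assert charge_fast / (charge_fast + charge_slow) < 1e-3
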