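"""Circuit-element extraction: direct formulas, the k/R_ms solver, the
simplified estimator, reversal voltages and the γ-sensitivity sweep."""

import copy
import math

import numpy as np
import pytest

import tubcap as tc
from tubcap.extract import UnphysicalFitError

from conftest import draw_physical_circuit


def grid_search_k_Rms(cr, gamma, k_range=(0.05, 5.0), n=400, refine=6):
    """Independent oracle: 2-D grid search minimizing the simultaneous
    residuals of the two R_ms(k) relations."""
    def joint_residual(k):
        Dk = cr.R_1 * k - cr.R_12
        if Dk == 0:
            return math.inf, math.nan
        R_ms = cr.R_1 * cr.R_12 * (gamma * k - 1.0) / Dk
        if R_ms <= cr.R_1:
            return math.inf, math.nan
        quad = (R_ms * R_ms
                - R_ms * (cr.R_1 + cr.R_2 + (cr.R_2 - cr.R_1) * gamma * k)
                + cr.R_1 * cr.R_2)
        return abs(quad) / (R_ms * R_ms), R_ms

    lo, hi = k_range
    best = None
    for _ in range(refine):
        ks = np.linspace(lo, hi, n)
        vals = [joint_residual(k)[0] for k in ks]
        i = int(np.argmin(vals))
        best = ks[i]
        lo = ks[max(i - 1, 0)]
        hi = ks[min(i + 1, n - 1)]
    return best, joint_residual(best)[1]


class TestDirectFormulas:
    def test_access_resistance_verification_circuit(self, verif_analytic_biexp):
        R_a = tc.access_resistance(verif_analytic_biexp, -80.0, -75.0)
        assert R_a == pytest.approx(12.5, rel=1e-10)

    def test_access_resistance_scale_invariance(self, verif_analytic_biexp):
        p = copy.deepcopy(verif_analytic_biexp)
        p.J_1 *= 2; p.J_2 *= 2; p.J_inf_1 *= 2; p.J_inf_2 *= 2
        R_a = tc.access_resistance(p, -80.0, -75.0)
        assert R_a == pytest.approx(12.5 / 2.0, rel=1e-10)

    def test_access_resistance_rejects_nonpositive_jump(self, verif_analytic_biexp):
        p = copy.deepcopy(verif_analytic_biexp)
        p.J_1, p.J_2 = -1.0, -0.1
        with pytest.raises(UnphysicalFitError):
            tc.access_resistance(p, -80.0, -75.0)

    def test_surface_capacitance_verification_circuit(self, verif_analytic_biexp):
        C_s, tau_s = tc.surface_capacitance(verif_analytic_biexp, 12.5)
        assert C_s == pytest.approx(74.0, rel=1e-10)
        assert tau_s == pytest.approx(925.0, rel=1e-10)

    def test_combined_resistances_verification_circuit(self, verif_analytic_biexp):
        R_a = tc.access_resistance(verif_analytic_biexp, -80.0, -75.0)
        C_s, tau_s = tc.surface_capacitance(verif_analytic_biexp, R_a)
        cr = tc.combined_resistances(verif_analytic_biexp, R_a, tau_s)
        assert cr.R_1 == pytest.approx(150.0 * 15.0 / 165.0, rel=1e-9)
        assert cr.R_2 == pytest.approx(150.0 * 256.0 / 406.0, rel=1e-9)
        assert 0 < cr.a < 1 and cr.b > 1
        assert 0 < cr.R_1 < cr.R_2

    def test_analytic_roundtrip_on_random_circuits(self):
        """Extraction applied to exact closed-form parameters recovers the
        resistance combinations of the generating circuit."""
        rng = np.random.default_rng(42)
        proto = tc.StepProtocol(tau_p=0.0)
        for _ in range(25):
            params = draw_physical_circuit(rng)
            r = tc.analytic_step_response(params, proto)
            p = tc.BiexpParams(J_1=r.J_1, J_2=r.J_2, tau_1=r.tau_1,
                               tau_2=r.tau_2, J_inf_2=r.J_inf_2,
                               J_inf_1=r.J_inf_1)
            R_a = tc.access_resistance(p, -80.0, -75.0)
            assert R_a == pytest.approx(params.R_a, rel=1e-8)
            C_s, tau_s = tc.surface_capacitance(p, R_a)
            cr = tc.combined_resistances(p, R_a, tau_s)
            R_1_true = params.R_ms * params.R_t / (params.R_ms + params.R_t)
            R_2_true = (params.R_ms * (params.R_t + params.R_mt)
                        / (params.R_ms + params.R_t + params.R_mt))
            assert cr.R_1 == pytest.approx(R_1_true, rel=1e-6)
            assert cr.R_2 == pytest.approx(R_2_true, rel=1e-6)


class TestKSolver:
    def test_verification_circuit_k_and_Rms(self, verif_analytic_biexp, verif_circuit):
        res = tc.extract_elements(verif_analytic_biexp, -80.0, -75.0,
                                  verif_circuit.gamma)
        assert res.k == pytest.approx(46.0 / 74.0, rel=1e-6)
        assert res.R_ms == pytest.approx(150.0, rel=1e-6)

    def test_quadratic_residual_bound(self, verif_result):
        cr = verif_result.combined
        g, k = verif_result.gamma_expected, verif_result.k
        R_ms = verif_result.R_ms
        resid = (R_ms**2 - R_ms * (cr.R_1 + cr.R_2 + (cr.R_2 - cr.R_1) * g * k)
                 + cr.R_1 * cr.R_2)
        assert abs(resid) < 1e-8 * R_ms**2

    def test_agrees_with_grid_search_oracle(self, verif_result):
        cr = verif_result.combined
        for gamma in (0.5, 0.7, 1.0, 1.25):
            k_solver, Rms_solver, _ = tc.solve_k_Rms(cr, gamma)
            k_grid, Rms_grid = grid_search_k_Rms(cr, gamma)
            assert k_solver == pytest.approx(k_grid, rel=1e-4)
            assert Rms_solver == pytest.approx(Rms_grid, rel=1e-4)

    def test_no_physical_intersection_raises(self):
        cr = tc.CombinedResistances(R_1=5.0, R_2=60.0, a=0.5, b=2.0,
                                    tau_s=900.0, R_12=5.0)
        with pytest.raises(UnphysicalFitError, match="no physical"):
            tc.solve_k_Rms(cr, 1.0)


class TestDerivedElements:
    def test_verification_circuit_elements(self, verif_result):
        assert verif_result.C_s == pytest.approx(74.0, rel=0.01)
        assert verif_result.C_t == pytest.approx(46.0, rel=0.01)
        assert verif_result.R_t == pytest.approx(15.0, rel=0.01)
        assert verif_result.R_mt == pytest.approx(241.0, rel=0.01)
        assert verif_result.C_m == pytest.approx(120.0, rel=0.01)
        assert verif_result.f_t == pytest.approx(46.0 / 120.0, rel=0.01)

    def test_f_t_monotone_in_k(self):
        ks = np.linspace(0.01, 5.0, 50)
        f = ks / (1 + ks)
        assert np.all(np.diff(f) > 0)
        assert np.all((f > 0) & (f < 1))

    def test_Rms_below_R1_rejected(self, verif_result):
        with pytest.raises(UnphysicalFitError):
            tc.circuit_elements(0.6, verif_result.combined.R_1 * 0.9,
                                74.0, verif_result.combined, 1.0)


class TestSimplifiedEstimator:
    def test_exact_formula_with_true_parallel_resistance(
            self, verif_analytic_biexp, verif_circuit):
        """The un-simplified relation with the true R_mt||R_t reproduces
        C_t exactly on closed-form input."""
        p = verif_analytic_biexp
        R_par = verif_circuit.R_mt * verif_circuit.R_t / (verif_circuit.R_mt + verif_circuit.R_t)
        C_t = (p.tau_1 * p.J_2 + p.tau_2 * p.J_1) / (p.J_1 + p.J_2) / R_par
        assert C_t == pytest.approx(46.0, rel=1e-9)

    def test_substitution_error_is_small(self, verif_analytic_biexp):
        """Replacing R_mt||R_t by R_ms||R_t changes C_t by only a few
        percent in the physical regime."""
        R_1 = 150.0 * 15.0 / 165.0
        C_t = tc.tubular_capacitance_simplified(verif_analytic_biexp, R_1,
                                                k_c=1.0)
        assert C_t == pytest.approx(46.0, rel=0.05)

    def test_k_c_scales_linearly(self, verif_analytic_biexp):
        a = tc.tubular_capacitance_simplified(verif_analytic_biexp, 13.0, 1.0)
        b = tc.tubular_capacitance_simplified(verif_analytic_biexp, 13.0, 0.97)
        assert b / a == pytest.approx(0.97, rel=1e-12)


class TestReversalVoltage:
    def test_verification_circuit_reversal_voltage(self, verif_result):
        assert verif_result.U_rev == pytest.approx(-160.0, rel=0.01)
        assert abs(verif_result.U_rev_discrepancy) < 0.5

    def test_distinct_reversal_voltages_do_not_affect_capacitances(self, verif_circuit):
        """With U_ms != U_mt the single-reversal assumption breaks: the
        estimate falls between the two true values (and its internal
        consistency check stays ~0, since the two printed expressions are
        algebraically identical), while C_s and C_t are unaffected."""
        params = verif_circuit.replace(U_ms=-150.0, U_mt=-40.0)
        trace = tc.simulate_step(params, tc.StepProtocol())
        p = tc.fit_trace(trace)
        res = tc.extract_elements(p, -80.0, -75.0, params.gamma)
        assert abs(res.U_rev_discrepancy) < 1e-6
        assert -150.0 < res.U_rev < -40.0
        assert res.C_s == pytest.approx(74.0, rel=0.01)
        assert res.C_t == pytest.approx(46.0, rel=0.01)

    def test_zero_current_steady_state_returns_holding(
            self, verif_analytic_biexp):
        """If the pre-step steady current vanishes, the first estimate is
        exactly the holding voltage."""
        p = copy.deepcopy(verif_analytic_biexp)
        p.J_inf_1 = 0.0
        U_rev, disc = tc.reversal_voltage_estimate(p, 12.5, 0.88, -80.0, -75.0)
        est_1 = U_rev - disc / 2.0
        assert est_1 == pytest.approx(-80.0, abs=1e-12)


class TestGammaSweep:
    def test_C_s_constant_across_grid(self, verif_biexp):
        sweep = tc.gamma_sensitivity_sweep(
            verif_biexp, -80.0, -75.0, np.linspace(0.4, 1.25, 10))
        cs = [r.C_s for r in sweep.results]
        assert np.ptp(cs) < 1e-12 * cs[0]

    def test_solver_failures_recorded_not_raised(self, verif_biexp):
        grid = [1e-6, 0.7]  # absurd gamma fails, the physical one succeeds
        sweep = tc.gamma_sensitivity_sweep(verif_biexp, -80.0, -75.0, grid)
        assert (sweep.results[0] is None) == (sweep.errors[0] is not None)
        assert sweep.results[1] is not None

    def test_dataframe_and_error_summary(self, verif_biexp):
        sweep = tc.gamma_sensitivity_sweep(
            verif_biexp, -80.0, -75.0, np.linspace(0.5, 1.0, 5),
            reference={"C_t": 46.0, "f_t": 46.0 / 120.0, "C_s": 74.0})
        df = sweep.to_dataframe()
        assert {"gamma_expected", "C_t", "f_t"} <= set(df.columns)
        errs = sweep.max_relative_errors()
        assert set(errs) == {"C_t", "f_t", "C_s"}
        assert errs["C_s"] < 0.01


class TestGammaIndependence:
    def test_R_a_and_C_s_identical_for_any_gamma(self, verif_biexp):
        r1 = tc.extract_elements(verif_biexp, -80.0, -75.0, 0.5)
        r2 = tc.extract_elements(verif_biexp, -80.0, -75.0, 1.2)
        assert r1.R_a == r2.R_a
        assert r1.C_s == r2.C_s
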