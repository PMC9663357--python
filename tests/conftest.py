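import numpy as np
import pytest

import tubcap as tc


@pytest.fixture(scope="session")
def verif_circuit():
    """The published verification circuit."""
    return tc.VERIFICATION_CIRCUIT


@pytest.fixture(scope="session")
def step_protocol():
    return tc.StepProtocol(U_1=-80.0, U_2=-75.0, t_pre=5.0, t_step=20.0,
                           tau_p=0.05)


@pytest.fixture(scope="session")
def ideal_protocol():
    return tc.StepProtocol(U_1=-80.0, U_2=-75.0, t_pre=5.0, t_step=20.0,
                           tau_p=0.0)


@pytest.fixture(scope="session")
def verif_trace(verif_circuit, step_protocol):
    return tc.simulate_step(verif_circuit, step_protocol)


@pytest.fixture(scope="session")
def verif_ideal_trace(verif_circuit, ideal_protocol):
    return tc.simulate_step(verif_circuit, ideal_protocol)


@pytest.fixture(scope="session")
def verif_biexp(verif_trace):
    return tc.fit_trace(verif_trace)


@pytest.fixture(scope="session")
def verif_result(verif_biexp, verif_circuit):
    return tc.extract_elements(verif_biexp, -80.0, -75.0, verif_circuit.gamma)


@pytest.fixture(scope="session")
def verif_analytic_biexp(verif_circuit, ideal_protocol):
    """Exact six-parameter summary from the closed-form response."""
    resp = tc.analytic_step_response(verif_circuit, ideal_protocol)
    return tc.BiexpParams(
        J_1=resp.J_1, J_2=resp.J_2, tau_1=resp.tau_1, tau_2=resp.tau_2,
        J_inf_2=resp.J_inf_2, J_inf_1=resp.J_inf_1)


def draw_physical_circuit(rng: np.random.Generator) -> tc.CircuitParams:
    """Random circuit in the physical (sucrose) regime: R_mt, R_ms >> R_t
    and the conductance/capacitance proportionality coefficient in the
    range explored experimentally."""
    while True:
        R_a = rng.uniform(5.0, 25.0)
        R_t = rng.uniform(10.0, 80.0)
        R_ms = rng.uniform(75.0, 300.0)
        C_s = rng.uniform(40.0, 120.0)
        C_t = rng.uniform(20.0, 80.0)
        gamma = rng.uniform(0.4, 1.25)
        R_mt = (R_ms / gamma) * (C_s / C_t)
        if R_ms >= 4.0 * R_t and R_mt >= 4.0 * R_t:
            U = rng.uniform(-170.0, -100.0)
            return tc.CircuitParams(
                R_a=R_a, R_t=R_t, R_ms=R_ms, R_mt=R_mt,
                C_s=C_s, C_t=C_t, U_ms=U, U_mt=U)
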