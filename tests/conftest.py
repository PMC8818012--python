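import numpy as np
import pytest

from epifield.epileptor import EpileptorParams
from epifield.surrogates import SurrogateSpec, grid_sheet, make_flat_surrogate
from epifield.workflows import run_simulation_workflow

# Coarse meshes (0.8 mm edges) keep the suite fast; the generator defaults
# (sheet dimensions, electrode geometry, excitability values) are untouched.
COARSE = 0.8


def scalar_epileptor_rhs(z, p, u0):
    """Independent scalar Epileptor right-hand side (test oracle).

    Written from the model equations without reference to the package
    implementation: six coupled ODEs for (u1, u2, v, q1, q2, g) of an
    unconnected node.
    """
    u1, u2, v, q1, q2, g = z
    if u1 < 0:
        f1 = u1**3 - 3 * u1**2
    else:
        f1 = (q1 - 0.6 * (v - 4.0) ** 2) * u1
    f2 = 6.0 * (q1 + 0.25) if q1 >= -0.25 else 0.0
    du1 = (u2 - f1 - v + p.I_1) / p.tau_s
    du2 = (1.0 - 5.0 * u1**2 - u2) / p.tau_s
    dv = (4.0 * (u1 - u0) - v) / (p.tau_s * p.tau_0)
    dq1 = (-q2 + q1 - q1**3 + p.I_2 + 0.002 * g - 0.3 * (v - 3.5)) / p.tau_s
    dq2 = (-q2 + f2) / (p.tau_s * p.tau_2)
    dg = p.a_12 * u1 - g / (p.tau_s * p.tau_12)
    return np.array([du1, du2, dv, dq1, dq2, dg])


@pytest.fixture(scope="session")
def default_params():
    return EpileptorParams()


@pytest.fixture(scope="session")
def flat_coarse():
    """Flat surrogate surface + electrode at the coarse test resolution."""
    return make_flat_surrogate(SurrogateSpec(kind="flat", target_edge_length=COARSE))


@pytest.fixture(scope="session")
def small_sheet():
    """20 x 20 mm flat grid used for kernel and equilibrium checks."""
    return grid_sheet(20.0, 20.0, COARSE)


@pytest.fixture(scope="session")
def flat_seizure(flat_coarse):
    """Full seizure-spread run on the flat surrogate (shared across tests).

    gamma_11 = 0.8 corresponds to a clinically plausible ~6 mm/s ictal
    wavefront on this mesh; 20 s covers ignition, full recruitment of
    the electrode path (~13.5 s) and a few seconds of mature seizure.
    """
    surface, electrode = flat_coarse
    params = EpileptorParams(gamma_11=0.8)
    result, bip, onsets = run_simulation_workflow(
        surface, electrode, params, duration=20.0
    )
    return {
        "surface": surface,
        "electrode": electrode,
        "params": params,
        "result": result,
        "bipolar": bip,
        "onsets": onsets,
    }
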