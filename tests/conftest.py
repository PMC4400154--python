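import numpy as np
import pytest

from dlcact.dynamics import DEFAULT_TRUE_PARAMS, simulate
from dlcact.geometry import CycleSpec, build_schedule


@pytest.fixture(scope="session")
def schedule20():
    """Small half-axis (20 NC14 nuclei) for fast full simulations."""
    return build_schedule(n14=20)


@pytest.fixture(scope="session")
def schedule50():
    return build_schedule(n14=50)


@pytest.fixture(scope="session")
def true_params():
    return DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def traj20(schedule20, true_params):
    """One extended-variant trajectory shared across read-only tests."""
    return simulate(true_params, schedule20)


def make_cycle(n=1, A_n=1.0, V_n=1.0, V_C=1.0, A_m=1.0, cycle_id=14,
               interphase=10.0, mitosis=None):
    """Hand-built cycle spec for single-compartment and stoichiometry tests."""
    return CycleSpec(
        cycle_id=cycle_id, n_nuclei=n, interphase_duration=interphase,
        mitosis_duration=mitosis, A_n_tilde=A_n, V_n_tilde=V_n,
        V_C_tilde=V_C, A_m_tilde=A_m, compartment_length=1.0 / n, height=35.0,
    )
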