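import numpy as np
import pytest
from hypothesis import settings

import netpattern as npt

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def vpc():
    return npt.build_reflective_row(6, 1)


@pytest.fixture(scope="session")
def vpc_dec(vpc):
    return npt.decompose_network(vpc)


@pytest.fixture(scope="session")
def lattice8():
    return npt.build_torus_lattice(8, 8, npt.notch_lattice_stencil())


@pytest.fixture(scope="session")
def lattice8_dec(lattice8):
    return npt.decompose_network(lattice8)


@pytest.fixture(scope="session")
def notch_signs():
    return npt.LocalDynamics(
        np.array([["-", "-"], ["0", "-"]], dtype=object),
        np.array([["0", "0"], ["+", "0"]], dtype=object),
        sign_only=True,
    )


@pytest.fixture(scope="session")
def notch_numeric():
    return npt.LocalDynamics(
        np.array([[-1.0, -1.0], [0.0, -1.0]]),
        np.array([[0.0, 0.0], [1.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def delta_notch():
    return npt.make_delta_notch_model()
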