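import numpy as np
import pytest

import symrec as sr


@pytest.fixture(scope="session")
def r14_8_5():
    return sr.SymmetrySpec(N=14, n=8, nu=5)


@pytest.fixture(scope="session")
def tiny_library(r14_8_5):
    """11-coupling library around 10 kHz; small powder, desk-scale steps."""
    grid = np.arange(9900.0, 10100.0 + 1e-9, 20.0)
    return sr.build_library(
        r14_8_5, "1a", 115, 60e3, coupling_grid=grid,
        n_orient=30, n_gamma=2, points_per_rotor=120,
    )


@pytest.fixture(scope="session")
def recovery_library(r14_8_5):
    """Library spanning the synthetic-coupling range at the 20 Hz grid step."""
    grid = np.arange(9400.0, 11600.0 + 1e-9, 20.0)
    return sr.build_library(
        r14_8_5, "1a", 115, 60e3, coupling_grid=grid,
        n_orient=50, n_gamma=2, points_per_rotor=120,
    )
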