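import numpy as np
import pytest

from rootpatch import chemistry as ch
from rootpatch import mechanics as mech
from rootpatch.geometry import build_cell_domain, build_shell_mesh


@pytest.fixture(scope="session")
def small_domain():
    """60-compartment elongated cell, cheap enough for per-test integration."""
    return build_cell_domain(10.0, 2.0, 60, seed=1)


@pytest.fixture(scope="session")
def default_domain():
    """The standard 286-compartment symmetric tessellation."""
    return build_cell_domain(10.0, 2.0, 286, seed=1)


@pytest.fixture(scope="session")
def gradient_result():
    """Full gradient-mode patterning run (auxin, then ROP) at defaults."""
    return ch.simulate_patterning(mode="gradient")


#: Constant-auxin regime runs use an elongated cell (20 × 2 units): only
#: above the stationary-pattern wavelength (~11.5 units) does the uniform
#: state give way to a steady patterned state rather than oscillations.
REGIME_CELL = dict(length=20.0, width=2.0, n_compartments=286)


@pytest.fixture(scope="session")
def constant13_result():
    """Constant-auxin run at level 1.3 (the multi-peak regime)."""
    return ch.simulate_patterning(mode="constant", auxin_level=1.3, seed=0,
                                  **REGIME_CELL)


def _solve(E_inner, p_inner, n=40):
    mesh = build_shell_mesh(20.0, 0.5, (10.0, 10.0), 2.0, n)
    mats = {"inner": mech.MaterialParams(E_inner, 0.2),
            "outer": mech.MaterialParams(100.0, 0.2)}
    state = mech.solve_equilibrium(mesh, mats, mech.LoadField(0.2, p_inner))
    return state


@pytest.fixture(scope="session")
def baseline_state():
    return _solve(100.0, 0.2)


@pytest.fixture(scope="session")
def soft_state():
    return _solve(70.0, 0.2)


@pytest.fixture(scope="session")
def stiff_state():
    return _solve(130.0, 0.2)


@pytest.fixture(scope="session")
def pressure_soft_state():
    return _solve(70.0, 0.4)


@pytest.fixture(scope="session")
def pressure_stiff_state():
    return _solve(130.0, 0.4)


@pytest.fixture(scope="session")
def tiny_mesh():
    """8×8-element wall mesh for finite-difference and algebra checks."""
    return build_shell_mesh(20.0, 0.5, (10.0, 10.0), 2.0, 8)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
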