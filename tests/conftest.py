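"""Shared fixtures: the study's default emitter/stack and precomputed curves.

The calibration-curve family is expensive (a wavevector integral per
height, wavelength and slab thickness), so it is built once per session
and shared; individual curves are taken out of the inverter's families
rather than rebuilt.
"""

import numpy as np
import pytest

from giet import calibration as cal
from giet import materials
from giet.tcspc import IRFModel


@pytest.fixture(scope="session")
def emitter():
    return materials.atto655()


@pytest.fixture(scope="session")
def stack_spec():
    return cal.StackSpec()


@pytest.fixture(scope="session")
def irf():
    return IRFModel(sigma_ns=0.1, shift_ns=2.0)


@pytest.fixture(scope="session")
def inverter(emitter, stack_spec):
    inv = cal.ThicknessInverter(emitter, stack_spec)
    # realize the lazy families once so every test shares them
    assert len(inv.below_family) == len(inv.d_grid)
    assert len(inv.above_family) == len(inv.above_d_grid)
    return inv


@pytest.fixture(scope="session")
def none_curve(inverter):
    """Bare-substrate calibration curve on the default grid."""
    return inverter.above_family[0]


@pytest.fixture(scope="session")
def below8_curve(inverter):
    """Below-SLB curve for the thickest (8 nm) slab of the comparison family."""
    idx = int(np.argmin(np.abs(inverter.d_grid - 8.0)))
    assert inverter.d_grid[idx] == 8.0
    return inverter.below_family[idx]


@pytest.fixture(scope="session")
def coarse_z_grid(stack_spec):
    """A fast 0.25 nm grid for tests that do not need inversion accuracy."""
    return cal.default_z_grid(stack_spec, span_nm=30.0, step_nm=0.25)
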