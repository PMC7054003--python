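import numpy as np
import pytest

from myovstep.density import DensityModel, QuadratureSpec
from myovstep.lattice import ActinLattice
from myovstep.observables import StepModel
from myovstep.params import KineticRates, LoadForce, MotorParams

#: Reduced quadrature for tests that only need qualitative accuracy.
COARSE_QUAD = QuadratureSpec(n_r=8, n_alpha=96, n_psi=32, prune=1e-13)


@pytest.fixture(scope="session")
def params():
    return MotorParams()


@pytest.fixture(scope="session")
def rates():
    return KineticRates()


@pytest.fixture(scope="session")
def lattice():
    return ActinLattice()


@pytest.fixture(scope="session")
def model_f0(params, rates):
    """Wild-type analytic pipeline at zero load (shared, expensive)."""
    return StepModel(params, rates)


@pytest.fixture(scope="session")
def density_f0(model_f0):
    return model_f0.density


@pytest.fixture(scope="session")
def coarse_grid_f0(params):
    """Coarse 3-D density grid at zero load for projection tests."""
    model = DensityModel(params, LoadForce(), quad=COARSE_QUAD)
    return model.grid(spacing=4.0)
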