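import numpy as np
import pytest

from monofilm import Isotherm
from monofilm.synthetic import generate_isotherm, isotherm_preset

# pi * A = kT at 20 C expressed in Angstrom^2 * mN/m
KT_20C = 404.5


@pytest.fixture
def linear_isotherm() -> Isotherm:
    """Affine condensed branch pi = 2 (70 - A): A_lim = 70, slope 2."""
    area = np.linspace(69.75, 55.0, 60)
    return Isotherm(area=area, pressure=2.0 * (70.0 - area))


@pytest.fixture
def ideal_gas_isotherm() -> Isotherm:
    """2-D ideal gas pi A = kT: closed form Cs^-1 = pi, no collapse."""
    area = np.linspace(100.0, 20.0, 500)
    return Isotherm(area=area, pressure=KT_20C / area)


@pytest.fixture(scope="session")
def pc183_noiseless():
    spec = isotherm_preset("pc183_20C")
    return generate_isotherm(spec)


@pytest.fixture(scope="session")
def pc160_noiseless():
    spec = isotherm_preset("pc160_20C")
    return generate_isotherm(spec)
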