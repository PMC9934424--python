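import numpy as np
import pytest
import sympy as sp

from pbdna import ModelParams
from pbdna.params import SYM


@pytest.fixture(scope="session")
def unit_params():
    return ModelParams(a1=1.0, a2=1.0, eta=1.0, zeta=1.0)


@pytest.fixture(scope="session")
def criterion_grid():
    """The standard residual-check lattice: 400 x 50 over [-10,10] x [0,1]."""
    return np.linspace(-10.0, 10.0, 400), np.linspace(0.0, 1.0, 50)


@pytest.fixture(scope="session")
def benchmark_closed_form():
    from pbdna.benchmark import benchmark_params
    from pbdna.families import closed_form

    return closed_form(benchmark_params())


def omega_of(cf) -> float:
    return complex(sp.N(cf.omega)).real
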