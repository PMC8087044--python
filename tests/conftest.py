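import numpy as np
import pytest

import rametipm as rp


@pytest.fixture(scope="session")
def ref_params():
    return rp.reference_parameterization()


@pytest.fixture(scope="session")
def big_dataset(ref_params):
    """n=5000 synthetic census from the reference parameterization (seed 1)."""
    return rp.generate_population(ref_params, 5000, seed=1)


@pytest.fixture(scope="session")
def study_dataset(ref_params):
    """Study-scale synthetic census (276 ramets at t, seed 0)."""
    return rp.generate_population(ref_params, 276, seed=0)


@pytest.fixture(scope="session")
def ref_grid():
    """Default domain: observed size range [-6.04, 3.31] padded by 0.8."""
    return rp.make_grid(-6.84, 4.11, 100)


@pytest.fixture(scope="session")
def ref_kernels(ref_params, ref_grid):
    return rp.build_kernels(ref_params, ref_grid)
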