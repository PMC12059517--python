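import warnings

import pytest

from pbs_lfqa import (
    ErrorModelConfig,
    MachineGeometry,
    generate_plan,
    simulate_course,
)


@pytest.fixture(scope="session")
def geometry():
    return MachineGeometry()


@pytest.fixture(scope="session")
def small_plan():
    """2 horizontal fields, 3 layers x 40 spots each (240 spots)."""
    return generate_plan(2, [90.0, 270.0], 3, 40, 40.0, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_plan():
    """1 field, 2 layers x 12 spots (24 spots) for fast dose tests."""
    return generate_plan(1, [0.0], 2, 12, 25.0, rng_seed=5)


@pytest.fixture(scope="session")
def default_errors():
    return ErrorModelConfig(rng_seed=1)


@pytest.fixture(scope="session")
def zero_errors():
    return ErrorModelConfig.zero(rng_seed=1)


@pytest.fixture(scope="session")
def course(small_plan, geometry, default_errors):
    """Five simulated fractions of the small plan, default error model."""
    return simulate_course(small_plan, geometry, default_errors, 5)


@pytest.fixture()
def no_small_n_warning():
    """Silence the few-fractions advisory warning in statistics tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield
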