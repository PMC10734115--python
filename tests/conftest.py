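import numpy as np
import pytest

from cardioda.phantom import DomainAppearance, PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(grid_shape=(48, 48, 16), anatomy_seed=7)


@pytest.fixture(scope="session")
def noiseless_spec():
    apps = {
        "source": DomainAppearance(
            {0: 0.0, 1: 0.9, 2: 0.35, 3: 0.8, 4: 0.7, 5: 0.6, 6: 1.0}, 0.0, 0.0),
        "target": DomainAppearance(
            {0: 0.1, 1: 0.55, 2: 0.72, 3: 0.3, 4: 0.62, 5: 0.22, 6: 0.46}, 0.0, 0.0),
    }
    return PhantomSpec(grid_shape=(48, 48, 16), anatomy_seed=3, appearance=apps)


@pytest.fixture(scope="session")
def phantom_case(small_spec):
    return generate_phantom(small_spec, "target")


@pytest.fixture(scope="session")
def tiny_cohort():
    spec = PhantomSpec(grid_shape=(32, 32, 16))
    return generate_cohort(spec, n_source=3, n_target=4, paired=False, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
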