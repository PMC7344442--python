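import numpy as np
import pytest

from lucsim import reference, synthetic


@pytest.fixture(scope="session")
def rules():
    return reference.ecological_optimization_rules()


@pytest.fixture(scope="session")
def toy_spec():
    return synthetic.SyntheticScenarioSpec(grid_shape=(60, 60), seed=5,
                                           autocorrelation_scale=3.0)


@pytest.fixture(scope="session")
def toy_landscape(toy_spec):
    return synthetic.generate_landscape(toy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
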