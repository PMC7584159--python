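import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def o7_run():
    """One end-to-end inference on the published-inversion demo dataset,
    shared across tests (simulation -> synteny -> demarcation ->
    architecture -> mechanism call)."""
    from invbreak.inversion_sim import o7_config, simulate
    from invbreak.pipeline import infer

    config = o7_config(seed=7)
    inverted, uninverted, outgroup, truth = simulate(config)
    result = infer(inverted, uninverted, outgroup)
    return config, inverted, uninverted, outgroup, truth, result
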