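import numpy as np
import pytest

from fertqtl import synthetic_data as sd


@pytest.fixture(scope="session")
def small_cfg():
    return sd.small_preset(seed=11)


@pytest.fixture(scope="session")
def population(small_cfg):
    """One small simulated population with divergent lines, reused
    read-only across tests."""
    gm = sd.simulate_population(small_cfg)
    gm, truth = sd.simulate_divergent_lines(gm, small_cfg)
    return gm, truth


@pytest.fixture(scope="session")
def expression(small_cfg, population):
    gm, _ = population
    return sd.simulate_expression(gm, small_cfg)
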