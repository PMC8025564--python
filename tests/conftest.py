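import numpy as np
import pytest

from tepop.parameters import (
    DEFAULT_LEVEL_MAP,
    SimulationParams,
    make_effect_distribution,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20210407)


def small_params(**overrides) -> SimulationParams:
    """Desk-top-sized parameters for fast unit tests."""
    base = dict(
        progeny=1,
        excision_rate=0.0,
        death_rate=0.0,
        insertion_bias=None,
        mutation_rate=0.0,
        non_coding_fraction=0.5,
        mutation_effect=0.01,
        carrying_capacity=20,
        genome_length=100,
        initial_te_per_host=2,
        transposition_rate=0.0,
        effect_distribution=make_effect_distribution(0.0),
        max_generations=50,
    )
    base.update(overrides)
    return SimulationParams(**base)


@pytest.fixture
def scaled_level_map():
    """Default calibration with a small carrying capacity for fast designs."""
    lm = dict(DEFAULT_LEVEL_MAP)
    lm["carrying_capacity"] = (50, 100)
    return lm
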