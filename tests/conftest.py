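import pytest

from farmsoc import SynthConfig, simulate
from farmsoc.indicators import compute_indicators
from farmsoc.predict import predict_at_points


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(seed=11, n_regions=4, n_farms_per_region=80, n_points=300)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_indicators(small_config, small_sim):
    return compute_indicators(small_sim.farms, small_config.crops,
                              small_config.excretion, small_sim.tillage)


@pytest.fixture(scope="session")
def small_predicted(small_config, small_sim, small_indicators):
    return predict_at_points(small_sim.points, small_sim.farms, small_indicators,
                             region_centroids=small_sim.regions,
                             crops=small_config.crops)
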