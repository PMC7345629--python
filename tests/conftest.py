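import numpy as np
import pytest

from bmiradar import (
    MetricRegions,
    ScanConfig,
    estimate_propagation_speed,
    simulate_scan,
    standard_fixtures,
    time_of_flight,
    to_time_domain,
)

SEED = 20260101


@pytest.fixture(scope="session")
def reduced_config():
    return ScanConfig.reduced()


@pytest.fixture(scope="session")
def speed(reduced_config):
    return estimate_propagation_speed(reduced_config)


@pytest.fixture(scope="session")
def delays(reduced_config, speed):
    return time_of_flight(reduced_config, speed)


@pytest.fixture(scope="session")
def fixtures():
    return standard_fixtures(SEED)


@pytest.fixture(scope="session")
def three_scatterer(fixtures):
    return fixtures["three-scatterer"]


@pytest.fixture(scope="session")
def three_scatterer_sinogram(three_scatterer):
    """Noiseless calibrated envelope sinogram of the three-scatterer phantom."""
    fx = three_scatterer
    full, ref = simulate_scan(fx.phantom, fx.config, noise_sigma=0.0, seed=fx.seed)
    return to_time_domain(full, ref, fx.config.time_grid)


@pytest.fixture(scope="session")
def three_scatterer_regions(three_scatterer):
    tumor = three_scatterer.phantom.tumor
    return MetricRegions.from_config(
        three_scatterer.config, tumor.position, tumor.radius
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
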