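import pytest

from ncdproj.synthetic import NoiseConfig, SimulationConfig, generate_all, make_ground_truth


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_provinces=3, seed=7)


@pytest.fixture(scope="session")
def bundle(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig(
        n_provinces=3,
        seed=7,
        noise=NoiseConfig(deaths=False, surveys=False),
        province_effect_sd=0.0,
        exposure_province_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_bundle(noiseless_config):
    return generate_all(noiseless_config)


@pytest.fixture(scope="session")
def truth(small_config):
    return make_ground_truth(small_config)
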