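import numpy as np
import pytest

from schooltravel import CityConfig, ScenarioSpec, build_city


@pytest.fixture(scope="session")
def default_config():
    return CityConfig()


@pytest.fixture(scope="session")
def baseline_city():
    """One seeded default city (3000 households, 4 evenly placed schools)."""
    return build_city(CityConfig(seed=11))


def tiny_config(n_households=3, seed=5, **overrides):
    """A 240 m toy city: 5x5 roads, 4 segments of 3 cells per road."""
    params = dict(
        city_size_m=240.0,
        n_roads_per_axis=5,
        segments_per_road=4,
        cells_per_segment=3,
        cell_size_m=20.0,
        n_schools=1,
        n_households=n_households,
        seed=seed,
    )
    params.update(overrides)
    return CityConfig(**params)


def tiny_city(n_households=3, seed=5, **overrides):
    config = tiny_config(n_households=n_households, seed=seed, **overrides)
    scenario = ScenarioSpec(n_schools=config.n_schools,
                            n_households=config.n_households,
                            zone_layout=(1, 1))
    return build_city(config, scenario)


@pytest.fixture
def toy_city():
    return tiny_city()
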