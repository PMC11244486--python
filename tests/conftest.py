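import numpy as np
import pytest

from tillerscan import PlantSpec, generate_plant


@pytest.fixture(scope="session")
def small_plant():
    """A modest 9-tiller plant used by several extraction tests."""
    spec = PlantSpec(tiller_count=9, height=0.8, crown_radius=0.27,
                     point_spacing=0.003, seed=3)
    cloud, truth = generate_plant(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def default_plant():
    """The default mid-season spec (12 tillers, 0.9 m)."""
    spec = PlantSpec(seed=7)
    cloud, truth = generate_plant(spec)
    return spec, cloud, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
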