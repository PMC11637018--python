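import numpy as np
import pytest

from uamt3d.backbone import NetworkSpec, build_network
from uamt3d.phantoms import PhantomSpec


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_spec():
    """Smallest network that still has two resolution levels."""
    return NetworkSpec(levels=2, base_channels=2, sam_kernel=3)


@pytest.fixture(scope="session")
def tiny_net(tiny_spec):
    return build_network(tiny_spec, seed=0)


@pytest.fixture(scope="session")
def small_phantom_spec():
    return PhantomSpec(volume_shape=(32, 32, 12), n_cases=6,
                       labeled_fraction=0.5, test_fraction=0.0, seed=5)
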