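import numpy as np
import pytest

from wmdissect.io import ReferenceGrid
from wmdissect.phantom import demo_spec, make_scene, scene_registry
from wmdissect.voi import ParcellationVolume


@pytest.fixture(scope="session")
def demo_scene():
    return make_scene(demo_spec(seed=7))


@pytest.fixture(scope="session")
def demo_registry():
    return scene_registry(demo_spec(seed=7))


@pytest.fixture
def identity_grid():
    return ReferenceGrid((16, 16, 16), np.eye(4))


@pytest.fixture
def toy_parcellation(identity_grid):
    data = np.zeros((16, 16, 16), dtype=np.int32)
    data[2:5, 2:5, 2:5] = 3
    data[10:13, 10:13, 10:13] = 5
    return ParcellationVolume(data, identity_grid, labels={"a": 3, "b": 5})
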