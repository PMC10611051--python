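import numpy as np
import pytest

from cvcroparea import BinaryCropMap, SceneConfig, generate_scene
from cvcroparea.grid import SceneGrid


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic scene shared across tests (fixed seed)."""
    return generate_scene(SceneConfig(seed=7))


@pytest.fixture
def unit_grid():
    def make(height=10, width=10, pixel=1.0):
        return SceneGrid(0.0, 0.0, pixel, -pixel, width, height, "EPSG:32618")

    return make


@pytest.fixture
def crop_map_factory(unit_grid):
    def make(labels):
        labels = np.asarray(labels, dtype=np.uint8)
        return BinaryCropMap(unit_grid(*labels.shape), labels)

    return make
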