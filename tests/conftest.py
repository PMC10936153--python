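import numpy as np
import pytest

from hyphacoloc import presets
from hyphacoloc.synthetic_scene import make_scene, render


@pytest.fixture(scope="session")
def truth_scene():
    """Scene designed for exact ground-truth comparisons (uniform vesicles,
    generous gaps, no ring, no green cytosol)."""
    return make_scene(presets.scene_objects_truth(seed=2))


@pytest.fixture(scope="session")
def noiseless_pair(truth_scene):
    return render(truth_scene, presets.acq_noiseless())


@pytest.fixture(scope="session")
def standard_scene():
    return make_scene(presets.scene_spec(0.5, seed=1))


@pytest.fixture(scope="session")
def standard_pair(standard_scene):
    return render(standard_scene, presets.acq_standard(seed=11))


def random_mask(rng, shape=(16, 16, 16), p=0.3):
    return rng.random(shape) < p
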