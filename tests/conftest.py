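import numpy as np
import pytest

from hsiprep import phantom
from hsiprep.cube_io import crop
from hsiprep.pipeline import correct_scene


@pytest.fixture(scope="session")
def default_scene():
    """The reference phantom scene at the default study conditions, seed 1."""
    spec = phantom.SceneSpec(rng_seed=1)
    cube, truth = phantom.render_scene(spec)
    return spec, cube, truth


@pytest.fixture(scope="session")
def corrected_sample(default_scene):
    """Double-plate-corrected reflectance cube cropped to the seed region,
    with the matching per-pixel truth label map."""
    spec, cube, truth = default_scene
    corrected, _ = correct_scene(cube, spec)
    s0, s1 = spec.sample_x_interval
    sample = crop(corrected, x_range=(s0, s1))
    return sample, truth.label_map[s0:s1, :], truth.foreground_mask.grid[s0:s1, :]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
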