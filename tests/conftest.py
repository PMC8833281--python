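import numpy as np
import pytest

from cathrecon.phantom import PhantomConfig, generate_phantom, rasterize_truth_mask
from cathrecon.pipeline import geometry_from_truth


@pytest.fixture(scope="session")
def small_phantom():
    """A compact 5-catheter phantom shared by read-only tests."""
    cfg = PhantomConfig(shape=(64, 64, 24), n_catheters=5, insertion_range_mm=(14.0, 18.0),
                        rng_seed=11)
    t1w, t2w, paths = generate_phantom(cfg)
    return cfg, t1w, t2w, paths


@pytest.fixture(scope="session")
def small_phantom_masks(small_phantom):
    cfg, _, _, paths = small_phantom
    return rasterize_truth_mask(paths, cfg.shape, radius=2.0)


@pytest.fixture(scope="session")
def small_geometry(small_phantom):
    _, _, _, paths = small_phantom
    return geometry_from_truth(paths)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
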