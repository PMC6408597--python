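import numpy as np
import pytest

import camosim as cs


@pytest.fixture(scope="session")
def palette():
    return cs.generate_synthetic_palette(8, 100, seed=1)


@pytest.fixture(scope="session")
def base_colors(palette):
    return cs.select_base_colors(palette, seed=1)


@pytest.fixture(scope="session")
def small_texture_params():
    # sub-sigma raster is intentional for speed; tests silence the warning
    return cs.TextureParams(width=256, height=64, sigma=8.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
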