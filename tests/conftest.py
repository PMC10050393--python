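import numpy as np
import pytest

from her2mil.imaging import SpotImage
from her2mil.stain import RUIFROK_HDAB, od_to_rgb
from her2mil.synthetic import SyntheticSpotSpec, generate_spot


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hdab():
    return RUIFROK_HDAB


@pytest.fixture(scope="session")
def small_spot():
    """A 96 px score-3 synthetic spot (3x3 grid of 32 px tiles)."""
    spec = SyntheticSpotSpec(score=3, side_px=96, tile_size=32, seed=7)
    image, label = generate_spot(spec)
    return image, label, spec


@pytest.fixture(scope="session")
def two_stain_image():
    """Synthetic image mixing the two reference stain vectors with random
    positive weights spanning nearly-pure extremes."""
    r = np.random.default_rng(99)
    h, d = RUIFROK_HDAB.stain_matrix[0], RUIFROK_HDAB.stain_matrix[1]
    ch = r.uniform(0.01, 1.2, 6000)
    cd = r.uniform(0.01, 1.2, 6000)
    od = ch[:, None] * h + cd[:, None] * d
    return SpotImage(od_to_rgb(od.reshape(60, 100, 3)), "two_stain")
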