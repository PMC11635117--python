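import numpy as np
import pytest

from deeppath import synthetic
from deeppath.slide_prep import SlideRaster


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disk_slide():
    """1024x1024 white slide with one saturated red disk of radius 200."""
    H = W = 1024
    img = np.full((H, W, 3), 255, dtype=np.uint8)
    yy, xx = np.mgrid[:H, :W]
    disk = (yy - 512) ** 2 + (xx - 512) ** 2 <= 200**2
    img[disk] = (200, 20, 30)
    return SlideRaster(pixels=img, slide_id="disk"), disk


@pytest.fixture(scope="session")
def small_bags():
    return synthetic.make_bags(synthetic.BagSpec(n_bags=40, n_instances=20,
                                                 dim=16, seed=7))


@pytest.fixture(scope="session")
def expression_cohort():
    return synthetic.make_expression_cohort(synthetic.ExpressionSpec(
        n_samples=60, seed=5))
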