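import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def disc_mask():
    """Filled disc of radius 100 px on a 256x256 grid, scale 1 mm/px."""
    from seedshape.raster import BinaryMask

    yy, xx = np.mgrid[:256, :256]
    return BinaryMask((xx - 128.0) ** 2 + (yy - 128.0) ** 2 <= 100.0**2, 1.0)


@pytest.fixture(scope="session")
def small_lot():
    """A rendered 20-seed FERO1 lot (coarse scale) with its ground truth."""
    from seedshape.synth import model_lot_spec, render_population

    spec = model_lot_spec("FERO1", mean_length_mm=2.16, cv_length_pct=4.12,
                          rng_seed=42, mm_per_px=0.02)
    img, truth = render_population(spec)
    return spec, img, truth
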