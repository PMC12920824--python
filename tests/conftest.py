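import numpy as np
import pytest

from thermoclass.image import Thermogram
from thermoclass.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_image():
    """Smooth random 32x32 thermogram."""
    from scipy.ndimage import gaussian_filter

    g = np.random.default_rng(7).random((32, 32))
    g = gaussian_filter(g, 1.5)
    g = (g - g.min()) / (g.max() - g.min())
    return Thermogram(g)


@pytest.fixture()
def hotspot_phantom():
    spec = PhantomSpec(height=64, width=64, n_hotspots=3,
                       hotspot_radius_px=(4.0, 6.0), hotspot_delta=(0.3, 0.4),
                       background_gradient=0.05, noise_sd=0.01, seed=42)
    return generate_phantom(spec)


@pytest.fixture()
def flat_phantom():
    spec = PhantomSpec(height=64, width=64, n_hotspots=0,
                       background_gradient=0.0, noise_sd=0.0, seed=42)
    return generate_phantom(spec)[0]
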