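import numpy as np
import pytest

from neoseg.phantom import PhantomConfig, render_phantom


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale phantom: small enough for fast rendering, big enough
    for two non-overlapping lesions."""
    return PhantomConfig(
        image_height=160,
        image_width=160,
        n_lesions=2,
        vessel_branching_depth=3,
        lesion_radius_range=(8.0, 12.0),
        lesion_vessel_count=6,
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return render_phantom(small_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
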