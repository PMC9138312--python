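import numpy as np
import pytest

from fibrilfrag import (
    FibrilPopulation,
    FragmentationParams,
    RenderConfig,
    lay_contours,
    render_heightmap,
)


@pytest.fixture(scope="session")
def wt_params():
    """Rate-law parameters of the least fragmentation-resistant type."""
    return FragmentationParams(gamma=2.7, alpha=9.1e-4)


@pytest.fixture(scope="session")
def small_population():
    rng = np.random.default_rng(42)
    n = 50
    return FibrilPopulation(
        time=0.0,
        lengths=rng.uniform(150, 1200, n),
        heights=rng.normal(7.8, 0.3, n),
    )


@pytest.fixture(scope="session")
def clean_render_config():
    """Noise- and background-free frame for geometric oracles."""
    return RenderConfig(
        image_px=512, scan_size=2500.0, noise_sd=0.0, background_coeffs=(0.0, 0.0, 0.0)
    )


@pytest.fixture(scope="session")
def default_render_config():
    """Default-statistics frame at reduced size (same 4.88 nm pixels)."""
    return RenderConfig(image_px=512, scan_size=2500.0)


@pytest.fixture(scope="session")
def rendered_scene(small_population, default_render_config):
    """A deposited, rendered scene with known ground truth."""
    contours = lay_contours(
        small_population, default_render_config, seed=7, min_separation=40.0,
        deposition_margin=600.0,
    )
    hmap = render_heightmap(contours, default_render_config, seed=8)
    return small_population, contours, hmap
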