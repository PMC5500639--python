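import numpy as np
import pytest

from phenonet import RenderConfig, RosettePhenotype, generate_dataset, render_rosette


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plain_config():
    """Noise-free plain-background renderer: exact masks for oracles."""
    return RenderConfig(image_size=64, background_style="plain", noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def small_count_dataset():
    """60 arabidopsis-style counting samples at 64 px, shared read-only."""
    return generate_dataset(
        60, "count", "arabidopsis_like", RenderConfig(image_size=64, seed=0), seed=11
    )


@pytest.fixture
def single_rosette(plain_config):
    return render_rosette(RosettePhenotype(leaf_count=1, age_hours=500), plain_config)
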