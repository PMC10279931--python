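import numpy as np
import pytest

from tmflow import synthetic as syn


@pytest.fixture
def small_geometry() -> syn.FlatMountGeometry:
    """Reduced flat-mount geometry (~2.12 mm circumference, 10 bins)."""
    return syn.FlatMountGeometry(
        image_size_px=(1100, 1100),
        pixel_size_um=1.3,
        band_mean_radius_px=260.0,
        band_height_um=278.0,
    )


@pytest.fixture
def noiseless_model() -> syn.FieldModel:
    return syn.FieldModel(noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
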