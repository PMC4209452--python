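import numpy as np
import pytest

from biofluo.phantom_sim import (
    AcquisitionSpec,
    CameraModel,
    IlluminationField,
    PhantomSpec,
    default_image_shape,
)


@pytest.fixture
def phantom() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture
def camera() -> CameraModel:
    return CameraModel(quantum_scale=50.0, hot_pixel_rate_per_px_s=2e-6)


@pytest.fixture
def acquisition() -> AcquisitionSpec:
    return AcquisitionSpec(exposure_s=0.5)


@pytest.fixture
def flat_illum(phantom, camera) -> IlluminationField:
    return IlluminationField.flat(default_image_shape(phantom, camera.pixel_size_mm))


@pytest.fixture
def vignette_illum(phantom, camera) -> IlluminationField:
    return IlluminationField.vignette(
        default_image_shape(phantom, camera.pixel_size_mm), 0.5
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def background_region(shape):
    h, w = shape
    return slice(2, max(3, h // 4)), slice(w // 4, 3 * w // 4)
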