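import numpy as np
import pytest

from ricevigor import (
    ScaleCalibration,
    SegmentationParams,
    View,
    ViewImage,
    generate_scene,
)


@pytest.fixture(scope="session")
def default_scene():
    """One default synthetic three-view scene (mild noise)."""
    return generate_scene(seed=11)


@pytest.fixture(scope="session")
def unit_calibration():
    return ScaleCalibration(mm_per_pixel=1.0)


@pytest.fixture()
def tenth_mm_calibration():
    return ScaleCalibration(mm_per_pixel=0.1)


def make_view_image(pixels, view=View.TOP, genotype="G", replicate=1, das=14):
    return ViewImage(
        pixels=np.asarray(pixels, dtype=float),
        view=view,
        genotype=genotype,
        replicate=replicate,
        das=das,
    )


@pytest.fixture()
def green_on_dark():
    """64×64 dark image with a solid 20×20 green square."""
    img = np.full((64, 64, 3), 0.02)
    img[20:40, 20:40] = (0.1, 0.5, 0.1)  # hue 120°, sat 0.8, val 0.5
    return make_view_image(img)
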