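import numpy as np
import pytest

from plaquekit.segmentation import BinaryMask, LabelMask
from plaquekit.synthetic import SceneParams, generate_scene


def rasterized_disk(radius: int, pad: int = 3) -> np.ndarray:
    """Boolean disk: pixels whose center lies within ``radius`` of the center."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def as_mask(pixels, pixel_size_um=1.0, channel="test") -> BinaryMask:
    return BinaryMask(np.asarray(pixels, bool), pixel_size_um, channel)


def as_label(pixels, pixel_size_um=1.0) -> LabelMask:
    pixels = np.asarray(pixels, int)
    return LabelMask(pixels, int(pixels.max()), pixel_size_um)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free five-plaque scene with full ground truth (session-cached)."""
    params = SceneParams(
        image_height_px=640,
        image_width_px=640,
        pixel_size_um=0.5,
        n_plaques=5,
        thios_positive_fraction=1.0,
        noise_sigma=0.0,
        background_microglia_density_per_mm2=20.0,
        dn_annulus=(2.0, 6.0),
        channel_intensities={
            "abeta": (8000.0, 400.0),
            "thios": (10000.0, 300.0),
            "iba1": (6000.0, 400.0),
            "hoechst": (9000.0, 350.0),
            "ki67": (7000.0, 300.0),
            "lamp1": (7500.0, 350.0),
        },
        ki67_fraction=0.3,
        seed=20240527,
    )
    img, truth = generate_scene(params)
    return params, img, truth
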