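import numpy as np
import pytest

from cystiquant.quantify import SlideImage, quantify_slide
from cystiquant.synthetic import SlideSpec, render_slide


@pytest.fixture(scope="session")
def small_slide():
    """One rendered marker slide with ~200 cells of each class."""
    spec = SlideSpec(
        width_px=768,
        height_px=768,
        microns_per_pixel=0.92,
        n_positive_cells=100,
        n_negative_cells=100,
        seed=42,
    )
    image, truth = render_slide(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def quantified_slide(small_slide):
    spec, image, truth = small_slide
    slide = SlideImage(image, spec.microns_per_pixel, "CD3")
    density, nuclei = quantify_slide(slide, truth.tissue_mask)
    return spec, truth, density, nuclei


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20151120)
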