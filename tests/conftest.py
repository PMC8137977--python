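"""Shared fixtures: synthetic lesions rendered once per session."""

import warnings

import numpy as np
import pytest

from mcnvquant.binarize import BinarizeParams
from mcnvquant.synthetic import RenderNoise, generate_network, render_octa

warnings.filterwarnings("ignore", category=FutureWarning)

CLEAN = RenderNoise(speckle_sigma=0.0, background_level=0.0, blur_px=0.0)


@pytest.fixture(scope="session")
def medusa_truth():
    return generate_network("medusa", seed=7)


@pytest.fixture(scope="session")
def medusa_clean(medusa_truth):
    """Noise-free render of the medusa fixture: (truth, image, lesion)."""
    img, lesion = render_octa(medusa_truth, noise=CLEAN)
    return medusa_truth, img, lesion


@pytest.fixture(scope="session")
def medusa_noisy(medusa_truth):
    img, lesion = render_octa(medusa_truth)
    return medusa_truth, img, lesion


@pytest.fixture(scope="session")
def clean_params():
    return BinarizeParams.clean()
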