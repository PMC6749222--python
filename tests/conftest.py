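import numpy as np
import pytest

from handvein import PipelineConfig, extract_capture, generate_subject, render_capture
from handvein.synthetic import ZERO_NOISE


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def subject():
    """One fixed synthetic subject used across tests."""
    return generate_subject(42)


@pytest.fixture(scope="session")
def clean_capture(subject):
    """Zero-noise render of the fixed subject plus its ground truth."""
    return render_capture(subject, 0, ZERO_NOISE)


@pytest.fixture(scope="session")
def clean_result(clean_capture, config):
    """Full pipeline extraction of the zero-noise capture."""
    img, _ = clean_capture
    return extract_capture(img, config)


@pytest.fixture(scope="session")
def noisy_capture(subject):
    return render_capture(subject, 1)


def random_blob(rng, shape=(40, 40), smooth=3.0, frac=0.35):
    """Random binary blob image: thresholded smoothed noise."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.standard_normal(shape), smooth)
    return field > np.quantile(field, 1.0 - frac)
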