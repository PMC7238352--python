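"""Shared phantom fixtures for the feature and segmentation tests."""

import numpy as np
import pytest

from birads_cad.imaging import extract_contour
from birads_cad.synthfix import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def ideal_disc():
    """Noise-free, blur-free disc phantom: the cleanest possible lesion."""
    roi, mask, meta = make_phantom(
        PhantomSpec(category="B2", radius_px=20, noise_sigma=0.0, edge_blur_sigma=0.0, seed=11)
    )
    return roi, mask, meta


@pytest.fixture(scope="session")
def ideal_disc_contour(ideal_disc):
    _, mask, _ = ideal_disc
    return extract_contour(mask)


@pytest.fixture(scope="session")
def spiculated_phantom():
    """Irregular, sharp-edged lesion (shape axis only perturbed)."""
    roi, mask, meta = make_phantom(
        PhantomSpec(
            category="B5",
            radius_px=20,
            amplitude=5.0,
            edge_blur_sigma=0.0,
            noise_sigma=0.0,
            seed=12,
        )
    )
    return roi, mask, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
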