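import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dotsynapse import simgen

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PX = 0.16  # μm/px used throughout the tests


@pytest.fixture(scope="session")
def lattice():
    """Study-condition lattice: 2 μm pitch, 0.75 μm dots, 40/10 mol/μm²."""
    return simgen.LatticeSpec()


@pytest.fixture(scope="session")
def dot_image(lattice):
    """One dot-array image with its ground-truth centroids."""
    return simgen.make_dot_array_image(lattice, seed=11)


@pytest.fixture(scope="session")
def uniform_cell(lattice):
    """RICM image, truth mask and (empty) patch sites of a uniform cell."""
    return simgen.make_ricm_image("uniform", lattice, cell_radius=8.0, seed=7)


@pytest.fixture(scope="session")
def cell_mask(uniform_cell):
    return uniform_cell[1]


def gaussian_spot(shape, center_px, sigma_px, amp, bg=0.0):
    """Noiseless single Gaussian spot, used as a hand-built oracle image."""
    rr = np.arange(shape[0])[:, None] - center_px[0]
    cc = np.arange(shape[1])[None, :] - center_px[1]
    return bg + amp * np.exp(-(rr**2 + cc**2) / (2.0 * sigma_px**2))
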