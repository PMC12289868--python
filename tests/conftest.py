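"""Shared fixtures: small phantoms and hand-built label volumes."""

import numpy as np
import pytest

from coralpore.segmentation import AIR, MASK, MICROPORE, SOLID, PhaseLabelVolume
from coralpore.synthetic_data import SyntheticTruth, generate_phantom

VOX_UM = 24.3


@pytest.fixture(scope="session")
def small_phantom():
    """A banded phantom small enough for unit tests (seconds, not minutes)."""
    truth = SyntheticTruth(seed=7, band_center_mm=1.8, band_width_mm=1.0)
    tomo, labels = generate_phantom(truth, (100, 100, 230), voxel_size_um=VOX_UM)
    return truth, tomo, labels


@pytest.fixture(scope="session")
def noiseless_phantom():
    truth = SyntheticTruth(seed=11, band_center_mm=2.0, noise_sd=0.0)
    tomo, labels = generate_phantom(truth, (100, 100, 230), voxel_size_um=VOX_UM)
    return truth, tomo, labels


def make_label_volume(n_solid, n_micro, n_air, n_mask, shape, voxel_size_um=180.0):
    """Build a PhaseLabelVolume with exact phase counts laid out in C order."""
    total = int(np.prod(shape))
    assert n_solid + n_micro + n_air + n_mask == total
    flat = np.concatenate([
        np.full(n_solid, SOLID, dtype=np.int16),
        np.full(n_micro, MICROPORE, dtype=np.int16),
        np.full(n_air, AIR, dtype=np.int16),
        np.full(n_mask, MASK, dtype=np.int16),
    ])
    return PhaseLabelVolume(
        labels=flat.reshape(shape), voxel_size_um=voxel_size_um, fragment_id="synthetic"
    )
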