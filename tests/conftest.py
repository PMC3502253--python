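"""Shared fixtures: sphere phantoms and small scenes built at test time."""

import numpy as np
import pytest

from hotpvc import PsfModel, VoxelGrid, gaussian_smooth


def make_sphere_grid(
    n: int = 49,
    spacing: float = 4.0,
    radius_mm: float = 20.0,
    amplitude: float = 8.0,
    background: float = 1.0,
    centre_offset_mm=(0.0, 0.0, 0.0),
):
    """Sharp homogeneous sphere on a flat background, centred mid-grid."""
    x = spacing * np.arange(n)
    c = [spacing * (n - 1) / 2.0 + o for o in centre_offset_mm]
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2)
    mask = r <= radius_mm
    values = np.where(mask, amplitude, background)
    return VoxelGrid(values, (spacing,) * 3), mask


@pytest.fixture(scope="session")
def sphere40():
    """Sharp 40 mm diameter sphere, contrast 8:1, 4 mm voxels."""
    return make_sphere_grid(radius_mm=20.0)


@pytest.fixture(scope="session")
def blurred_sphere40(sphere40):
    """The same sphere after 8 mm FWHM PSF blurring (noiseless)."""
    grid, mask = sphere40
    return gaussian_smooth(grid, PsfModel(8.0)), mask
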