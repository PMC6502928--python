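"""Shared fixtures: small phantoms and acquisition configs.

Heavy phantoms are session-scoped so they are generated once; all
generation is seeded, so every test run sees identical data.
"""

import numpy as np
import pytest

from cardioxpci import AcquisitionConfig, Volume3D
from cardioxpci import phantom as ph


@pytest.fixture(scope="session")
def lr_acq():
    """Low-resolution whole-heart acquisition geometry."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def fiber_texture_z():
    """Straight-fibre texture along z with 5% noise, plus ground truth."""
    spec = ph.PhantomSpec(shape=(64, 64, 64), noise_sigma=0.05, seed=7)
    return ph.make_fiber_texture(spec, (1.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def ventricle_ramp():
    """160^3 annulus with a +60 -> -60 transmural helical-angle ramp."""
    spec = ph.PhantomSpec(shape=(160, 160, 160), noise_sigma=0.05, seed=5,
                          wall_inner_radius=120.0, wall_outer_radius=440.0)
    return spec, *ph.make_ventricle_phantom(spec)


@pytest.fixture(scope="session")
def collagen_phantom_small():
    """64^3 dual-rendering collagen phantom at 5% collagen."""
    spec = ph.PhantomSpec(shape=(64, 64, 64), collagen_fraction=0.05,
                          noise_sigma=0.05, seed=11)
    return ph.make_collagen_phantom(spec)


@pytest.fixture(scope="session")
def disc_volume(lr_acq):
    """Two-slice volume holding an off-centre binary disc."""
    N = 128
    yy, xx = np.indices((N, N))
    disc = (((yy - 70) ** 2 + (xx - 55) ** 2) < 30 ** 2).astype(float)
    return Volume3D(np.stack([disc, disc]), voxel_size=lr_acq.pixel_size_um)
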