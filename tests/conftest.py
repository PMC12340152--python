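import numpy as np
import pytest
import scipy.ndimage as ndi

import liquidstem as ls
from liquidstem import virtual_scope as vs


@pytest.fixture(scope="session")
def calibration_phantom():
    """Axisymmetric scene: tilting changes nothing but imposed shifts."""
    return vs.make_calibration_phantom(seed=0)


@pytest.fixture(scope="session")
def slab_bead_phantom():
    """Membrane-supported bead phantom (beads near the eucentric plane)."""
    return ls.make_bead_phantom(
        25, box_nm=(128.0, 128.0, 128.0), bead_radius_nm=6.0, seed=11,
        voxel_size_nm=2.0, thickness_nm=24.0,
    )


@pytest.fixture(scope="session")
def textured_image():
    rng = np.random.default_rng(1)
    return ndi.gaussian_filter(rng.normal(size=(128, 128)), 1.5)


@pytest.fixture(scope="session")
def clean_series(slab_bead_phantom):
    """Noise-free, drift-free, aligned tilt series of the bead slab."""
    plan = ls.make_tilt_plan(-60, 60, 4)
    return vs.acquire_series(slab_bead_phantom, plan, controller=None, seed=4)
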