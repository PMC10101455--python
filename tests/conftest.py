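"""Shared fixtures: phantom configurations used across the suite.

All imaging fixtures are generated at test time by the phantom simulator;
nothing is read from disk except what the tests themselves write.
"""

import numpy as np
import pytest

from nmvol.phantom import PhantomSpec, generate_subject, make_atlases


def quiet_spec(**overrides) -> PhantomSpec:
    """Deterministic phantom: no motion, no blur, no texture, and noise only
    in the reference region (keeps σ_ref defined while structures stay
    noise-free, so threshold segmentation is exact)."""
    defaults = dict(
        motion_sd=(0.0, 0.0),
        blur_fwhm=0.0,
        texture_amplitude=0.0,
        background_sd=0.0,
        ref_region_sd=0.5,
        seed=11,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def default_subject():
    """One subject at the full default spec (motion, noise, texture)."""
    spec = PhantomSpec(seed=7)
    measurements, truth = generate_subject(spec)
    return spec, measurements, truth


@pytest.fixture(scope="session")
def quiet_subject():
    spec = quiet_spec()
    measurements, truth = generate_subject(spec)
    return spec, measurements, truth


@pytest.fixture(scope="session")
def default_atlases():
    spec = PhantomSpec(seed=7)
    return make_atlases(spec)


def structure_points_world(truth, image) -> np.ndarray:
    """World coordinates (3×N) of the structure+reference voxels."""
    roi = truth.snc_mask.data | truth.lc_mask.data | truth.ref_mask.data
    idx = np.argwhere(roi).T.astype(float)
    return image.affine[:3, :3] @ idx + image.affine[:3, [3]]
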