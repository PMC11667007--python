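import numpy as np
import pytest
from scipy import ndimage

from segcurate import Case, Mask, PhantomParams, Volume, generate_cohort


def random_blob_mask(rng: np.random.Generator, shape=(12, 12, 12),
                     spacing=(1.0, 1.0, 1.0), ensure_nonempty=True) -> Mask:
    """A random connected-ish blob: thresholded smoothed noise."""
    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=2.0)
    cut = np.quantile(field, 0.85)
    vox = field > cut
    if ensure_nonempty and not vox.any():
        vox[tuple(s // 2 for s in shape)] = True
    return Mask(vox, spacing)


def random_sparse_mask(rng: np.random.Generator, shape=(16, 16, 16),
                       p=0.3) -> Mask:
    return Mask(rng.random(shape) < p, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def tiny_params() -> PhantomParams:
    """Small, fast phantom configuration for unit tests."""
    return PhantomParams(grid_shape=(32, 32, 32), radius_mm=5.0,
                         lateral_offset_mm=2.0, margin_voxels=6)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    cases, manifest = generate_cohort(10, tiny_params, seed=42,
                                      proportions=(6, 2, 2))
    return cases, manifest
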