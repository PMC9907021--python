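import numpy as np
import pytest

from contourbench import BinaryMask, TruthShapeConfig, generate_truth_mask
from contourbench.simulate import simulate_observer_bernoulli


def make_mask(voxels, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return BinaryMask(np.asarray(voxels, dtype=bool), spacing, origin)


def random_mask(rng, shape=(12, 12, 12), density=0.3, spacing=(1.0, 1.0, 1.0),
                origin=(0.0, 0.0, 0.0)):
    vox = rng.random(shape) < density
    return BinaryMask(vox, spacing, origin)


def random_blob_mask(rng, shape=(14, 14, 14), spacing=(1.0, 1.0, 1.0)):
    """A random connected-ish blob: thresholded smoothed noise (nonempty)."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
    vox = field > np.quantile(field, 0.8)
    if not vox.any():
        vox[tuple(s // 2 for s in shape)] = True
    return BinaryMask(vox, spacing)


@pytest.fixture(scope="session")
def sphere_truth_48():
    """16 mm-radius sphere on a 48^3 grid at 1.5 mm isotropic spacing."""
    return generate_truth_mask(
        TruthShapeConfig(
            grid_shape=(48, 48, 48), spacing=(1.5, 1.5, 1.5),
            family="sphere", size_mm=(16.0, 16.0, 16.0), seed=0,
        )
    )


@pytest.fixture(scope="session")
def sphere_truth_32():
    """10 mm-radius sphere on a 32^3 grid at 1.5 mm isotropic spacing."""
    return generate_truth_mask(
        TruthShapeConfig(
            grid_shape=(32, 32, 32), spacing=(1.5, 1.5, 1.5),
            family="sphere", size_mm=(10.0, 10.0, 10.0), seed=0,
        )
    )


def bernoulli_raters(truth, n, p=0.90, q=0.99, seed0=100):
    return [
        simulate_observer_bernoulli(truth, p, q, seed0 + j) for j in range(n)
    ]
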