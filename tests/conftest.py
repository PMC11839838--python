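import numpy as np
import pytest

import promptseg as ps
from promptseg._seeds import derive_seed


@pytest.fixture(scope="session")
def small_phantom():
    params = ps.PhantomParams(grid_shape=(40, 40, 32), tumor_radius_mm=8, seed=7)
    return ps.generate_phantom(params, "fix0")


@pytest.fixture(scope="session")
def norm_phantom(small_phantom):
    return ps.normalize_volume(small_phantom)


@pytest.fixture(scope="session")
def transverse_samples(norm_phantom):
    return ps.extract_slices(norm_phantom, "transverse")


@pytest.fixture
def predictor_factory():
    """Build a mock predictor with the given samples pre-registered."""

    def make(samples, **mock_kwargs):
        registry = ps.SliceRegistry()
        for s in samples:
            registry.register_sample(s)
        params = ps.MockPredictorParams(**mock_kwargs)
        return ps.make_mock_predictor(params, registry)

    return make


def random_blob_mask(rng, shape=(32, 32), sigma=3.0):
    """A random (usually concave) blob with guaranteed fg and bg pixels."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)
    mask = field > np.quantile(field, 0.75)
    mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = False
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = True
    return mask


def brute_force_center(mask):
    """Independent oracle for the distance-transform argmax rule.

    All-pairs Euclidean distances from every foreground pixel to every
    background pixel; returns the set of argmax pixels (exact squared-int
    distances) with the lexicographically smallest first.
    """
    from scipy.spatial.distance import cdist

    fg = np.argwhere(mask)
    bg = np.argwhere(~mask)
    d2 = cdist(fg, bg, "sqeuclidean").min(axis=1).round().astype(int)
    best = d2.max()
    winners = [tuple(p) for p in fg[d2 == best]]
    return sorted(winners)


@pytest.fixture
def blob_masks():
    def make(n, seed, shape=(32, 32)):
        rng = np.random.default_rng(derive_seed(seed, "blobs"))
        return [random_blob_mask(rng, shape) for _ in range(n)]

    return make
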