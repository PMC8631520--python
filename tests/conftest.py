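import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from phyllotex.voi import QuantizedVOI, VolumeWithMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_volume_with_mask(rng, shape=(10, 10, 10), p_mask=0.7):
    """Random intensities with a random (nonempty) mask."""
    voxels = rng.normal(100.0, 25.0, shape)
    mask = rng.uniform(size=shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    return VolumeWithMask(voxels=voxels, mask=mask)


def quantized_from_dense(dense):
    """Build a QuantizedVOI directly from a dense level array (0 = outside)."""
    dense = np.asarray(dense, dtype=np.int64)
    coords = np.argwhere(dense > 0)
    levels = dense[dense > 0]
    return QuantizedVOI(
        coords=coords,
        levels=levels,
        shape=dense.shape,
        n_levels=max(int(dense.max()), 2),
    )


def random_quantized(rng, shape=(5, 5, 5), n_levels=4, p_mask=0.8):
    """Random small quantized VOI with holes, for oracle comparisons."""
    dense = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.uniform(size=shape) < p_mask
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    dense = dense * mask
    q = quantized_from_dense(dense)
    q.n_levels = n_levels
    return q
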