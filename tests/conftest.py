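import numpy as np
import pytest

import vent4d as v
from vent4d.core import build_partition


@pytest.fixture(scope="session")
def affine_phantom():
    """Noise-free 32^3 phantom under a 5% isotropic expansion (J = 1.157625)."""
    return v.make_phantom(shape=(32, 32, 32), noise_sd_hu=0.0, seed=1)


@pytest.fixture(scope="session")
def affine_partition(affine_phantom):
    return build_partition(affine_phantom.mask)


@pytest.fixture(scope="session")
def identity_phantom():
    return v.make_phantom(
        shape=(32, 32, 32),
        transform=v.AffineTransform(np.eye(3)),
        noise_sd_hu=0.0,
        seed=1,
    )


def random_affine_field(rng, shape=(12, 12, 12), max_shear=0.15):
    """A globally affine displacement field on a small unit-spaced grid."""
    from vent4d.core import DisplacementField

    while True:
        A = np.eye(3) + rng.uniform(-max_shear, max_shear, (3, 3))
        if np.linalg.det(A) > 0.3:
            break
    ax = [np.arange(float(s)) for s in shape]
    X = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    c = (np.asarray(shape) - 1) / 2.0
    u = (X - c) @ (A - np.eye(3)).T
    return DisplacementField(u, np.ones(3), np.zeros(3)), A
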