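import numpy as np
import pytest

from gtvcascade import BinaryMask, ImageVolume, PhantomSpec, generate_case


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_spec():
    return PhantomSpec.desk()


@pytest.fixture(scope="session")
def desk_case(desk_spec):
    """One deterministic desk-scale phantom shared across read-only tests."""
    return generate_case(desk_spec, seed=7)


def random_mask(rng, shape=(12, 12, 12), p=0.3, spacing=(1.0, 1.0, 1.0)):
    data = (rng.random(shape) < p).astype(np.uint8)
    return BinaryMask(data, spacing)


def ellipsoid_mask(shape, center, semiaxes, spacing=(1.0, 1.0, 1.0)):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    rho = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return BinaryMask((rho <= 1.0).astype(np.uint8), spacing)


def volume_from(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing)
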