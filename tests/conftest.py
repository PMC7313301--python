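import numpy as np
import pytest

from ccparc import phantoms
from ccparc.cc_isolation import CCMask


@pytest.fixture(scope="session")
def small_bundle():
    """A 128x128 phantom shared by read-only tests."""
    return phantoms.make_phantom(phantoms.PhantomSpec(size=(128, 128), seed=7))


@pytest.fixture()
def rectangle_mask():
    """10x60 axis-aligned rectangle inside a 20x70 frame (rows 5:15, cols 5:65)."""
    m = np.zeros((20, 70), dtype=bool)
    m[5:15, 5:65] = True
    return m


@pytest.fixture()
def rectangle_ccmask(rectangle_mask):
    return CCMask.from_mask(rectangle_mask)


def random_blob(rng, size=12):
    """A hole-free 8-connected blob for contour-tracing oracles."""
    from scipy import ndimage as ndi

    m = np.zeros((size, size), dtype=bool)
    m[tuple(rng.integers(3, size - 3, 2))] = True
    for _ in range(3 * size):
        m |= ndi.binary_dilation(m) & (rng.random((size, size)) < 0.6)
    m = ndi.binary_fill_holes(m)
    lab, n = ndi.label(m, structure=np.ones((3, 3)))
    sizes = ndi.sum(m, lab, index=range(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))
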