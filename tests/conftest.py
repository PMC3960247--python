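import numpy as np
import pytest

from colonyquant.geometry import WellImage


def make_well(values, well_id="T1", side=None):
    """Build a circular-mask WellImage whose masked pixels take ``values``.

    ``values`` is assigned to the disc pixels in raster order; pixels
    outside the mask are set to an arbitrary junk value (37) so tests
    prove that the mask is honoured.
    """
    values = np.asarray(values, dtype=np.uint8)
    n = values.size
    if side is None:
        side = int(np.ceil(2.4 * np.sqrt(n / np.pi))) + 4
    r = side / 2.4
    yy, xx = np.mgrid[:side, :side]
    mask = (xx - side / 2) ** 2 + (yy - side / 2) ** 2 < r**2
    if mask.sum() < n:
        raise AssertionError("disc too small for requested values")
    # shrink mask to exactly n pixels
    idx = np.flatnonzero(mask.ravel())[:n]
    m = np.zeros(side * side, dtype=bool)
    m[idx] = True
    px = np.full(side * side, 37, dtype=np.uint8)
    px[idx] = values
    return WellImage(well_id, px.reshape(side, side), m.reshape(side, side))


@pytest.fixture
def bimodal_well():
    """30% of pixels uniform on [60, 100], 70% uniform on [200, 240]."""
    rng = np.random.default_rng(42)
    n = 4000
    ncell = int(0.3 * n)
    vals = np.concatenate(
        [rng.integers(60, 101, ncell), rng.integers(200, 241, n - ncell)]
    )
    return make_well(vals), ncell, n
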