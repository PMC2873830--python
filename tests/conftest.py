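import numpy as np
import pytest

from geobuild.geometry import is_degenerate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_nondegenerate_base(rng, k=4, scale=5.0, min_quality=0.05):
    """A random k-point reference set that is comfortably non-degenerate."""
    while True:
        pts = rng.uniform(-scale, scale, size=(k, 3))
        if not is_degenerate(pts, rel_tol=min_quality):
            return pts


def unit_tetrahedron():
    return np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [0.5, np.sqrt(3) / 2, 0.0],
            [0.5, np.sqrt(3) / 6, np.sqrt(6) / 3],
        ]
    )
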