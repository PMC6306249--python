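import numpy as np
import pytest

from shapebias.synth import build_catalog


@pytest.fixture(scope="session")
def small_catalog():
    """4 blob classes x 6 exemplars, fixed seed (shared across tests)."""
    return build_catalog(4, 6, seed=11, blob_fraction=1.0)


@pytest.fixture(scope="session")
def disk_mask():
    h = w = 160
    yy, xx = np.mgrid[:h, :w]
    return ((yy - 80.0) ** 2 + (xx - 80.0) ** 2 <= 50.0 ** 2).astype(np.uint8)
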