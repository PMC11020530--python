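import numpy as np
import pytest

from fibrograd.geometry import (
    build_ellipsoid_lv,
    build_slab_mesh,
    segment_aha17,
    single_segment_hierarchy,
    split_layers,
    subdivide_segments,
)
from fibrograd.simulation import APParams


@pytest.fixture(scope="session")
def slab_mesh():
    """Small slab used by most simulation unit tests."""
    return build_slab_mesh((20, 20, 16), (1.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def slab_hierarchy(slab_mesh):
    return single_segment_hierarchy(slab_mesh)


@pytest.fixture(scope="session")
def lv_mesh():
    """Reference synthetic left ventricle (coarse but fully segmentable)."""
    return build_ellipsoid_lv((2.0, 2.0, 3.0), 0.9, (48, 48, 40))


@pytest.fixture(scope="session")
def lv_hierarchy(lv_mesh):
    h = segment_aha17(lv_mesh)
    h = subdivide_segments(h, lv_mesh)
    return split_layers(h, lv_mesh)


@pytest.fixture(scope="session")
def iso_params():
    return APParams(d_long=1.0, d_trans=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240416)
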