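import numpy as np
import pytest

from vasculomorph import PhantomSpec, Volume3D, ZoneParams, rasterize_tree
from vasculomorph.phantom import Segment, VesselTree


def make_tube(radius: float, length: float, shape=(64, 40, 40), spacing=(1.0, 1.0, 1.0),
              axis=0, margin=4.0):
    """A single axis-aligned capsule rasterized at the given grid."""
    center = np.array(shape, dtype=float) * np.asarray(spacing) / 2.0
    p0, p1 = center.copy(), center.copy()
    p0[axis] = margin
    p1[axis] = shape[axis] * spacing[axis] - margin
    tree = VesselTree([Segment(p0, p1, radius, "normal")])
    binary, labels, rad = rasterize_tree(tree, shape, spacing)
    return tree, binary


@pytest.fixture
def unit_tube():
    """Radius-3 axis-aligned tube on a unit-spacing grid."""
    return make_tube(3.0, 56.0)


@pytest.fixture
def small_phantom_spec():
    """A quick 2 mm³ phantom spec with a 500 µm tumor sphere."""
    return PhantomSpec(
        domain_size_um=(2000.0, 2000.0, 2000.0),
        spacing_um=(31.0, 31.0, 31.0),
        tumor_center_um=(1000.0, 1000.0, 1000.0),
        tumor_radius_um=500.0,
        transition_width_um=200.0,
        seed=3,
    )


@pytest.fixture
def ball_volume():
    """Digital ball of radius 10 voxels in a 31³ grid."""
    ii, jj, kk = np.meshgrid(*[np.arange(31)] * 3, indexing="ij")
    ball = ((ii - 15) ** 2 + (jj - 15) ** 2 + (kk - 15) ** 2 <= 100).astype(np.uint8)
    return Volume3D(ball, kind="binary")
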