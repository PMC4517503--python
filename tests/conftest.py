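import numpy as np
import pytest

from lvconsensus import Contour, SliceGeometry


@pytest.fixture
def geom() -> SliceGeometry:
    """1 mm isotropic pixels, 64x64 image, contiguous 8 mm slices."""
    return SliceGeometry((1.0, 1.0), 8.0, 8.0, 64, 64, 4)


@pytest.fixture
def geom_fine() -> SliceGeometry:
    """1.25 mm pixels on an 80x80 image (100 mm FOV)."""
    return SliceGeometry((1.25, 1.25), 10.0, 10.0, 80, 80, 4)


def make_circle(radius, center=(50.0, 50.0), n=64, surface="endo",
                frame="ED", slice_index=0) -> Contour:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(theta),
                           center[1] + radius * np.sin(theta)])
    return Contour(surface, frame, slice_index, pts)


def make_square(side, corner=(10.0, 10.0), surface="endo", frame="ED",
                slice_index=0) -> Contour:
    x0, y0 = corner
    pts = np.array([[x0, y0], [x0 + side, y0],
                    [x0 + side, y0 + side], [x0, y0 + side]])
    return Contour(surface, frame, slice_index, pts)


@pytest.fixture
def circle_factory():
    return make_circle


@pytest.fixture
def square_factory():
    return make_square
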