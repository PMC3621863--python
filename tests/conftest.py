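import numpy as np
import pytest
from shapely.geometry import Polygon

from lvquant import PhantomSpec, generate_phantom
from lvquant._geom import circle_polygon


@pytest.fixture(scope="session")
def cylinder_wedge_phantom():
    """Cylindrical LV with a fully transmural 90-degree wedge on all slices:
    both infarct fractions are analytically 25%."""
    spec = PhantomSpec(geometry="cylinder", infarct_angle_start=np.pi / 4,
                       infarct_angle_extent=np.pi / 2, infarct_transmurality=1.0,
                       infarct_slice_range=(0, 9), seed=11)
    return spec, generate_phantom(spec)


@pytest.fixture(scope="session")
def quiet_phantom():
    """No infarct, zero noise: every myocardial voxel is exactly remote_mean."""
    spec = PhantomSpec(infarct_transmurality=0.0, noise_sd=0.0, seed=3)
    return spec, generate_phantom(spec)


@pytest.fixture
def annulus():
    """Concentric 100-gon annulus, wall thickness exactly 1 mm."""
    epi = circle_polygon((5.0, 5.0), 3.0, 100)
    endo = circle_polygon((5.0, 5.0), 2.0, 100)
    return epi, endo


def ellipse_polygon(center, a, b, n=720):
    th = np.arange(n) * 2 * np.pi / n
    return Polygon(np.column_stack([center[0] + a * np.cos(th),
                                    center[1] + b * np.sin(th)]))
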