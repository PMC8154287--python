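import numpy as np
import pytest

from busfeat import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def disc_phantom():
    """Noise-free circular lesion (aspect 1, no speckle, no shadow)."""
    spec = PhantomSpec(seed=2)
    image, mask, contour = generate_phantom(spec)
    return spec, image, mask, contour


@pytest.fixture(scope="session")
def speckled_phantom():
    """Circular lesion with fully-developed speckle at 4 looks."""
    spec = PhantomSpec(seed=3, speckle_looks=4.0)
    image, mask, contour = generate_phantom(spec)
    return spec, image, mask, contour


@pytest.fixture
def circle_contour():
    """Finely sampled circle of radius 50 centered at (100, 100)."""
    theta = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
    return np.column_stack([100 + 50 * np.cos(theta), 100 + 50 * np.sin(theta)])


@pytest.fixture
def ellipse_contour():
    """Axis-aligned ellipse, semi-axes 40 (horizontal) and 20 (vertical)."""
    theta = np.linspace(0, 2 * np.pi, 1000, endpoint=False)
    return np.column_stack([100 + 40 * np.cos(theta), 100 + 20 * np.sin(theta)])
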