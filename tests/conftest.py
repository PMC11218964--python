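import numpy as np
import pytest

import chromring as cr


@pytest.fixture(scope="session")
def uniform_disk():
    """Clean uniform two-channel disk phantom analyzed end to end."""
    spec = cr.SyntheticSpec(radius_px=120, frame=320)
    image, bg_roi, truth = cr.generate_nucleus(spec)
    result = cr.analyze_image(image, bg_roi=bg_roi)
    return spec, image, bg_roi, truth, result


@pytest.fixture(scope="session")
def spheroid_stack():
    """8-slice spheroid phantom (3D), uniform profiles."""
    spec = cr.SyntheticSpec(shape="spheroid", n_slices=8, radius_px=100, frame=256)
    image, bg_roi, truth = cr.generate_nucleus(spec)
    result = cr.analyze_image(image, bg_roi=bg_roi)
    return spec, image, bg_roi, truth, result


def disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    """Rasterized disk under the package's pixel-centre convention."""
    size = 2 * (radius + pad)
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (xx + 0.5 - c) ** 2 + (yy + 0.5 - c) ** 2 <= radius**2


def random_convex_polygon(rng: np.random.Generator, n: int = 12, scale: float = 50.0):
    """Convex hull of random points, as a PolygonROI centred near (100, 100)."""
    from scipy.spatial import ConvexHull

    pts = rng.normal(100.0, scale / 3.0, size=(n, 2))
    hull = ConvexHull(pts)
    return cr.PolygonROI(pts[hull.vertices])
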