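import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import droppack as dp

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(autouse=True)
def _quiet_skimage_warnings(recwarn):
    # scikit-image deprecation chatter is irrelevant to the assertions
    import warnings

    warnings.filterwarnings("ignore", category=FutureWarning)
    yield


@pytest.fixture(scope="session")
def hex_network():
    """Noiselessly rendered perfect hexagonal 10x10 first layer."""
    spec = dp.LatticeSpec(
        lattice_type="hexagonal", nx=10, ny=10, spacing=45.0, droplet_radius=25.0, seed=1
    )
    return dp.synthesize_network(spec)


@pytest.fixture(scope="session")
def square_network():
    spec = dp.LatticeSpec(
        lattice_type="square", nx=10, ny=10, spacing=42.0, droplet_radius=25.0, seed=1
    )
    return dp.synthesize_network(spec)


@pytest.fixture(scope="session")
def sparse_network():
    spec = dp.LatticeSpec(
        lattice_type="sparse", nx=6, ny=6, spacing=45.0, droplet_radius=25.0, seed=1
    )
    return dp.synthesize_network(spec)


@pytest.fixture(scope="session")
def hex_segmentation(hex_network):
    seg = dp.segment_network(hex_network.membrane_image)
    dp.classify_regions(seg)
    return seg


def brute_force_delaunay(points: np.ndarray) -> set:
    """O(n^4) empty-circumcircle triangulation oracle (general position only)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    scale = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
    tol = 1e-9 * scale
    triangles = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                if abs(area2) < tol * scale:
                    continue
                # circumcentre from the perpendicular-bisector equations
                d = 2.0 * area2
                ux = (
                    (a @ a) * (b[1] - c[1])
                    + (b @ b) * (c[1] - a[1])
                    + (c @ c) * (a[1] - b[1])
                ) / d
                uy = (
                    (a @ a) * (c[0] - b[0])
                    + (b @ b) * (a[0] - c[0])
                    + (c @ c) * (b[0] - a[0])
                ) / d
                centre = np.array([ux, uy])
                r = np.linalg.norm(a - centre)
                empty = True
                for m in range(n):
                    if m in (i, j, k):
                        continue
                    if np.linalg.norm(pts[m] - centre) < r - tol:
                        empty = False
                        break
                if empty:
                    triangles.add((i, j, k))
    return triangles
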