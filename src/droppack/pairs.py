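"""Contact-angle measurement from droplet-pair images.

Mirrors the bench workflow: find the two droplets in a bright-rim image,
fit a circle to each droplet's free monolayer arc (excluding the bilayer
chord where the droplets abut), and convert the fitted radii and centre
distance to the contact angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import binary_dilation, disk
from skimage.segmentation import watershed

from .errors import DetectionError
from .geometry import contact_angle_from_pair

__all__ = ["PairMeasurement", "measure_pair_image", "measure_pair_triple"]


@dataclass(frozen=True)
class PairMeasurement:
    R1: float
    R2: float
    L: float
    theta_deg: float


def _fit_circle(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Algebraic (Kasa) circle fit refined by geometric least squares."""
    if w is None:
        w = np.ones_like(x)
    A = np.column_stack([x, y, np.ones_like(x)]) * w[:, None]
    b = (x * x + y * y) * w
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r = np.sqrt(sol[2] + cx * cx + cy * cy)

    def resid(p):
        return (np.hypot(x - p[0], y - p[1]) - p[2]) * w

    fit = least_squares(resid, x0=[cx, cy, r])
    return fit.x  # cx, cy, r


def measure_pair_triple(R1: float, R2: float, L: float) -> PairMeasurement:
    """Contact angle from a measured (R1, R2, L) triple."""
    return PairMeasurement(R1=R1, R2=R2, L=L, theta_deg=contact_angle_from_pair(R1, R2, L))


def measure_pair_image(image, ridge_width: float = 3.0) -> PairMeasurement:
    """Measure (R1, R2, L, theta) from a droplet-pair image.

    Thresholds the bright rim, splits the filled pair silhouette in two by
    watershed on the distance transform, fits one circle per droplet to the
    rim pixels intensity-weighted — masking out the zone where the two
    droplet masks abut (the bilayer chord) — and applies the pair-angle
    relation. Raises :class:`DetectionError` unless exactly two droplets
    are found.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise DetectionError("expected a 2D grayscale image")
    if img.max() <= img.min():
        raise DetectionError("featureless image")
    thr = threshold_otsu(img)
    bright = img > thr
    filled = ndi.binary_fill_holes(bright)
    lbl = label(filled)
    if lbl.max() == 0:
        raise DetectionError("no droplets found")
    sizes = np.bincount(lbl.ravel())
    sizes[0] = 0
    filled = lbl == np.argmax(sizes)

    dist = ndi.distance_transform_edt(filled)
    min_dist = max(3, int(0.5 * dist.max()))
    peaks = peak_local_max(dist, min_distance=min_dist, num_peaks=2, exclude_border=False)
    if len(peaks) != 2:
        raise DetectionError(f"found {len(peaks)} droplet cores, expected 2")
    markers = np.zeros_like(filled, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    ws = watershed(-dist, markers, mask=filled)

    # exclusion zone around the bilayer chord: where the two masks abut
    zone = binary_dilation(ws == 1, disk(2)) & binary_dilation(ws == 2, disk(2))
    zone = binary_dilation(zone, disk(int(2 * ridge_width)))

    fits = []
    for side in (1, 2):
        sel = bright & (ws == side) & ~zone
        ys, xs = np.nonzero(sel)
        if len(xs) < 10:
            raise DetectionError("too few rim pixels to fit a circle")
        cx, cy, r = _fit_circle(xs.astype(float), ys.astype(float), img[ys, xs])
        fits.append((cx, cy, r))
    (cx1, cy1, r1), (cx2, cy2, r2) = fits
    L = float(np.hypot(cx2 - cx1, cy2 - cy1))
    L = min(L, (r1 + r2) * (1.0 - 1e-12))  # clip sub-pixel overshoot past tangency
    theta = contact_angle_from_pair(r1, r2, L)
    return PairMeasurement(R1=float(r1), R2=float(r2), L=L, theta_deg=theta)
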