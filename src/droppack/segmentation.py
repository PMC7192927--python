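"""Segmentation of membrane-fluorescence images into droplets and oil inclusions.

The bright interconnected membranes (bilayers between touching droplets,
monolayer rims elsewhere) are enhanced with a Hessian-eigenvalue ridge
filter, thresholded, skeletonised and gap-closed; the enclosed dark regions
are the droplet interiors and trapped oil pockets. Regions are then told
apart morphologically: a region counts as a droplet iff its area lies
between 0.4x and 10x the median region area AND its convexity (region area
over convex-hull area) is at least 0.9; everything else is an oil inclusion.

Interactive cleanup is replaced by automated equivalents: sub-threshold
specks are dropped, single-pixel holes filled, and skeleton gaps up to a
configurable size closed. Border-touching regions are kept (whole first
layers are analysed, edges included) but carry a flag for optional exclusion.

Coordinates use the pixel-centre convention: origin at the top-left,
x = column, y = row, 0-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.filters import sato, threshold_otsu

from .errors import GeometryError, InsufficientDataError

__all__ = [
    "SegmentationParams",
    "NetworkSegmentation",
    "NetworkStats",
    "enhance_ridges",
    "segment_network",
    "classify_regions",
    "droplet_excess",
    "size_cv",
    "oil_fraction",
    "network_stats",
]

REGION_COLUMNS = [
    "id",
    "x",
    "y",
    "area_px2",
    "perimeter_px",
    "convexity",
    "class",
    "border",
]


@dataclass(frozen=True)
class SegmentationParams:
    ridge_scale_px: float = 2.0
    gap_close_px: int = 3
    min_region_px2: float = 5.0


@dataclass
class NetworkSegmentation:
    """Label image plus per-region table for one first-layer network."""

    label_image: np.ndarray
    regions: pd.DataFrame
    pixel_size_um: float | None = None
    notes: list = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class NetworkStats:
    """Defect statistics of one network's first layer."""

    N: int
    N_t: int | None
    droplet_excess_pct: float | None
    size_cv_pct: float | None
    oil_fraction: float


def enhance_ridges(image, ridge_scale_px: float = 2.0) -> np.ndarray:
    """Bright-line (ridge) response via Hessian-eigenvalue filtering.

    Returns the response normalised to [0, 1]; a featureless image maps to
    all zeros. Being derivative-based, the response is invariant to a global
    intensity offset.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {img.shape}")
    if ridge_scale_px <= 0:
        raise ValueError("ridge_scale_px must be positive")
    resp = sato(img, sigmas=[ridge_scale_px], black_ridges=False)
    peak = resp.max()
    return resp / peak if peak > 0 else np.zeros_like(resp)


def segment_network(
    image, params: SegmentationParams | None = None, pixel_size_um: float | None = None
) -> NetworkSegmentation:
    """Segment a membrane image into enclosed regions.

    Thresholds the ridge response (Otsu), skeletonises the membrane mask,
    closes gaps up to ``gap_close_px``, and labels the enclosed regions.
    The surrounding background — the connected component(s) of non-membrane
    pixels reaching the image corners — is discarded. An image with no
    enclosed regions yields an empty table with a warning note rather than
    an exception.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    resp = enhance_ridges(img, params.ridge_scale_px)

    empty = pd.DataFrame(columns=REGION_COLUMNS)
    if resp.max() == 0:
        note = "no ridge response; empty segmentation"
        warnings.warn(note)
        return NetworkSegmentation(
            np.zeros(img.shape, dtype=int), empty, pixel_size_um, [note]
        )

    thr = threshold_otsu(resp)
    mask = resp > thr
    # fill only speck-sized dropouts inside the ridge band (droplet interiors
    # are legitimate holes of the membrane mask and must survive)
    inv_labels = measure.label(~mask, connectivity=1)
    inv_sizes = np.bincount(inv_labels.ravel())
    tiny = inv_sizes <= 2
    tiny[0] = False
    mask = mask | tiny[inv_labels]
    skel = morphology.skeletonize(mask)
    if params.gap_close_px > 0:
        closed = morphology.closing(skel, morphology.disk(params.gap_close_px))
        skel = morphology.skeletonize(skel | closed)

    interior = ~skel
    labels = measure.label(interior, connectivity=1)

    # background = components reaching the image corners
    corners = {labels[0, 0], labels[0, -1], labels[-1, 0], labels[-1, -1]} - {0}
    for bg in corners:
        labels[labels == bg] = 0

    props = measure.regionprops(labels)
    h, w = labels.shape
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=int)
    next_id = 1
    for p in props:
        if p.area < params.min_region_px2:
            continue
        minr, minc, maxr, maxc = p.bbox
        rows.append(
            {
                "id": next_id,
                "x": p.centroid[1],
                "y": p.centroid[0],
                "area_px2": float(p.area),
                "perimeter_px": float(p.perimeter),
                "convexity": float(p.solidity),
                "class": "unclassified",
                "border": bool(minr == 0 or minc == 0 or maxr == h or maxc == w),
            }
        )
        keep[p.label] = next_id
        next_id += 1
    labels = keep[labels]

    notes = []
    if not rows:
        notes.append("no enclosed regions found")
        warnings.warn(notes[-1])
        return NetworkSegmentation(labels, empty, pixel_size_um, notes)
    return NetworkSegmentation(labels, pd.DataFrame(rows), pixel_size_um, notes)


def classify_regions(seg):
    """Assign droplet/inclusion classes in place and return the segmentation.

    A region is a droplet iff ``0.4 * median_area <= area <= 10 * median_area``
    and ``convexity >= 0.9``; all other regions are oil inclusions. The median
    is taken over all regions before any classification. Accepts either a
    :class:`NetworkSegmentation` or a bare region DataFrame.
    """
    df = seg.regions if isinstance(seg, NetworkSegmentation) else seg
    if len(df) == 0:
        return seg
    med = float(df["area_px2"].median())
    is_droplet = (
        (df["area_px2"] >= 0.4 * med)
        & (df["area_px2"] <= 10.0 * med)
        & (df["convexity"] >= 0.9)
    )
    df["class"] = np.where(is_droplet, "droplet", "inclusion")
    return seg


def droplet_excess(N: int, N_t: int) -> float:
    """Signed droplet excess 100 * (N - N_t) / N_t in percent."""
    if N_t <= 0:
        raise GeometryError("expected droplet count N_t must be positive")
    if N < 0:
        raise GeometryError("observed droplet count must be non-negative")
    return 100.0 * (N - N_t) / N_t


def size_cv(areas) -> float:
    """Droplet-size coefficient of variation in percent (sample SD / mean)."""
    a = np.asarray(areas, dtype=float)
    if a.size < 2:
        raise InsufficientDataError("size CV needs at least 2 droplet areas")
    return 100.0 * float(np.std(a, ddof=1)) / float(np.mean(a))


def oil_fraction(seg) -> float:
    """Fraction of total region area occupied by oil inclusions."""
    df = seg.regions if isinstance(seg, NetworkSegmentation) else seg
    if len(df) == 0:
        return 0.0
    if (df["class"] == "unclassified").any():
        raise ValueError("regions must be classified before computing the oil fraction")
    total = float(df["area_px2"].sum())
    inc = float(df.loc[df["class"] == "inclusion", "area_px2"].sum())
    return inc / total if total > 0 else 0.0


def network_stats(seg, N_t: int | None = None) -> NetworkStats:
    """Defect statistics (droplet excess, size CV, oil fraction) for one network."""
    df = seg.regions if isinstance(seg, NetworkSegmentation) else seg
    droplets = df[df["class"] == "droplet"]
    n = int(len(droplets))
    excess = droplet_excess(n, N_t) if N_t is not None else None
    cv = size_cv(droplets["area_px2"]) if n >= 2 else None
    return NetworkStats(
        N=n,
        N_t=N_t,
        droplet_excess_pct=excess,
        size_cv_pct=cv,
        oil_fraction=oil_fraction(df),
    )
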