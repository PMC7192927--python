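"""Delaunay-based classification of local droplet packing.

Each Delaunay triangle over the droplet centres is a triplet of neighbouring
droplets (its circumcircle contains no other centre) and is classified from
three dimensionless metrics:

* ``theta_max`` — the largest interior angle (60 deg for an equilateral
  triplet, 90 deg for a square-lattice triplet),
* ``A_hat`` — triangle area normalised by the mean droplet area,
* ``P_hat`` — triangle perimeter normalised by the mean droplet radius
  (equivalent-circle radii sqrt(area/pi)).

Classes and thresholds:

* hexagonal:  60 <= theta_max < 67
* amorphous:  67 <= theta_max < 83
* square:     83 <= theta_max < 97

and, for all three close-packed classes, ``0.25 < A_hat < 0.75`` together
with the sliver rule ``P_hat < 3.73 + 0.0545 * theta_max`` that rejects
skinny triangles built from two close droplets plus one distant one.
Anything else — including degenerate (collinear) triplets — is "no packing".
Per-network summaries weight each class by triangle area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .errors import GeometryError, TriangulationError
from .segmentation import NetworkSegmentation, NetworkStats, classify_regions, network_stats

__all__ = [
    "CLASSES",
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "PackingSummary",
    "triangulate",
    "triangle_metrics",
    "classify_triangle",
    "triangle_table",
    "packing_area_fractions",
    "analyze_centroids",
    "analyze_network",
]

CLASSES = ("hexagonal", "square", "amorphous", "no_packing")


@dataclass(frozen=True)
class Thresholds:
    """Packing-classifier thresholds; the defaults are the standard rule set."""

    hex_max_deg: float = 67.0
    amorphous_max_deg: float = 83.0
    square_max_deg: float = 97.0
    a_hat_min: float = 0.25
    a_hat_max: float = 0.75
    sliver_intercept: float = 3.73
    sliver_slope: float = 0.0545

    @property
    def is_standard(self) -> bool:
        return self == Thresholds()


DEFAULT_THRESHOLDS = Thresholds()


@dataclass
class PackingSummary:
    """Per-network packing area fractions plus the underlying triangle table."""

    fractions: dict
    n_triangles: int
    n_droplets: int
    triangles: pd.DataFrame
    stats: NetworkStats | None = None


def triangulate(centroids) -> np.ndarray:
    """Delaunay triangulation of droplet centres; returns (m, 3) vertex indices."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise TriangulationError("centroids must be an (n, 2) array")
    if len(pts) < 3:
        raise TriangulationError(f"need at least 3 points, got {len(pts)}")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise TriangulationError(f"degenerate point set (collinear?): {exc}") from exc
    if tri.simplices.size == 0:
        raise TriangulationError("no triangles produced (collinear points)")
    return np.sort(tri.simplices, axis=1)


def triangle_metrics(vertices, droplet_areas):
    """(theta_max, A_hat, P_hat, area, degenerate) for one triangle.

    ``vertices`` is a (3, 2) array of droplet centres; ``droplet_areas`` the
    areas of all droplets in the network, used for the normalisations. The
    largest angle comes from the law of cosines. A zero-area (collinear)
    triplet is flagged degenerate and reported with theta_max = 180 deg.
    """
    v = np.asarray(vertices, dtype=float)
    if v.shape != (3, 2):
        raise ValueError("vertices must be a (3, 2) array")
    areas = np.asarray(droplet_areas, dtype=float)
    if areas.size < 1 or np.any(areas <= 0):
        raise ValueError("need at least one positive droplet area")

    sides = np.array(
        [
            np.linalg.norm(v[1] - v[2]),  # opposite vertex 0
            np.linalg.norm(v[0] - v[2]),
            np.linalg.norm(v[0] - v[1]),
        ]
    )
    if np.any(sides <= 0):
        raise ValueError("triangle has coincident vertices")
    area = 0.5 * abs(np.cross(v[1] - v[0], v[2] - v[0]))
    perimeter = float(sides.sum())

    mean_area = float(np.mean(areas))
    mean_radius = float(np.mean(np.sqrt(areas / math.pi)))
    a_hat = area / mean_area
    p_hat = perimeter / mean_radius

    degenerate = area <= 1e-12 * sides.max() ** 2
    if degenerate:
        return 180.0, float(a_hat), float(p_hat), float(area), True

    a = sides.max()
    b, c = np.sort(sides)[:2]
    cos_t = (b * b + c * c - a * a) / (2.0 * b * c)
    theta_max = math.degrees(math.acos(min(1.0, max(-1.0, cos_t))))
    return float(theta_max), float(a_hat), float(p_hat), float(area), False


def classify_triangle(
    theta_max: float, A_hat: float, P_hat: float, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> str:
    """Packing class of one triangle; a pure function of the three metrics."""
    t = thresholds
    if not (math.isfinite(theta_max) and math.isfinite(A_hat) and math.isfinite(P_hat)):
        return "no_packing"
    close_packed = (t.a_hat_min < A_hat < t.a_hat_max) and (
        P_hat < t.sliver_intercept + t.sliver_slope * theta_max
    )
    if not close_packed:
        return "no_packing"
    # theta_max >= 60 for any true triangle; tolerate representation error
    if 60.0 - 1e-9 <= theta_max < t.hex_max_deg:
        return "hexagonal"
    if t.hex_max_deg <= theta_max < t.amorphous_max_deg:
        return "amorphous"
    if t.amorphous_max_deg <= theta_max < t.square_max_deg:
        return "square"
    return "no_packing"


def triangle_table(
    centroids,
    simplices,
    droplet_areas,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Metrics and class for every triangle, as one tidy table."""
    pts = np.asarray(centroids, dtype=float)
    rows = []
    for v0, v1, v2 in np.asarray(simplices, dtype=int):
        theta, a_hat, p_hat, area, degen = triangle_metrics(
            pts[[v0, v1, v2]], droplet_areas
        )
        cls = "no_packing" if degen else classify_triangle(theta, a_hat, p_hat, thresholds)
        rows.append(
            {
                "v0": v0,
                "v1": v1,
                "v2": v2,
                "theta_max": theta,
                "A_hat": a_hat,
                "P_hat": p_hat,
                "area_px2": area,
                "degenerate": degen,
                "packing_class": cls,
            }
        )
    return pd.DataFrame(rows)


def packing_area_fractions(triangles: pd.DataFrame) -> dict:
    """Area-weighted fraction of each packing class; fractions sum to one."""
    if len(triangles) == 0:
        raise GeometryError("no triangles to summarise")
    total = float(triangles["area_px2"].sum())
    if total <= 0:
        raise GeometryError("zero total triangle area")
    return {
        cls: float(triangles.loc[triangles["packing_class"] == cls, "area_px2"].sum())
        / total
        for cls in CLASSES
    }


def analyze_centroids(
    centroids,
    droplet_areas,
    N_t: int | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> PackingSummary:
    """Triangulate droplet centres, classify every triplet, summarise fractions."""
    pts = np.asarray(centroids, dtype=float)
    simplices = triangulate(pts)
    table = triangle_table(pts, simplices, droplet_areas, thresholds)
    return PackingSummary(
        fractions=packing_area_fractions(table),
        n_triangles=len(table),
        n_droplets=len(pts),
        triangles=table,
    )


def analyze_network(
    seg: NetworkSegmentation,
    N_t: int | None = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> PackingSummary:
    """Full per-network analysis from a segmentation.

    Classifies regions if still unclassified, triangulates droplet centroids
    only (inclusions are excluded from the mesh), classifies every triplet,
    and attaches the defect statistics (droplet excess against ``N_t``, size
    CV, oil-inclusion area fraction).
    """
    if (seg.regions["class"] == "unclassified").any():
        classify_regions(seg)
    droplets = seg.regions[seg.regions["class"] == "droplet"]
    if len(droplets) < 3:
        raise TriangulationError(
            f"need at least 3 droplet regions, found {len(droplets)}"
        )
    summary = analyze_centroids(
        droplets[["x", "y"]].to_numpy(),
        droplets["area_px2"].to_numpy(),
        thresholds=thresholds,
    )
    summary.stats = network_stats(seg, N_t)
    return summary
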