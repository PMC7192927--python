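"""Localisation of packing types across repeated prints.

Workflow: rigidly register each print's droplet centroids to a reference
(rotation + translation only, so the network geometry is preserved),
rasterise each classified triangle into a per-class binary presence map,
sum the maps across prints, and bin the accumulated counts onto an idealised
hexagonal layout of the print design. Within each hexagonal bin the class
counts are normalised to proportions, so bins with data always sum to one
and the number of prints cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon

from .errors import LayoutError
from .packing import CLASSES

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "register_to_reference",
    "rasterize_class_map",
    "accumulate",
    "HexLayout",
    "HexBinMap",
    "bin_hexagonal",
]


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, counter-clockwise) followed by translation, no scaling."""

    rotation_deg: float = 0.0
    translation: tuple = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        t = math.radians(self.rotation_deg)
        return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        rot = self.rotation_deg + other.rotation_deg
        t = self.matrix @ np.asarray(other.translation) + np.asarray(self.translation)
        return RigidTransform(rotation_deg=rot, translation=(float(t[0]), float(t[1])))

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix.T
        t = -rinv @ np.asarray(self.translation)
        return RigidTransform(
            rotation_deg=-self.rotation_deg, translation=(float(t[0]), float(t[1]))
        )


@dataclass
class RegistrationResult:
    transform: RigidTransform
    converged: bool
    rms: float
    n_iter: int


def _kabsch_2d(moving: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rotation+translation mapping moving onto target (no scaling)."""
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    H = (moving - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, d]) @ U.T
    t = tc - R @ mc
    angle = math.degrees(math.atan2(R[1, 0], R[0, 0]))
    return RigidTransform(rotation_deg=angle, translation=(float(t[0]), float(t[1])))


def _principal_angle(points: np.ndarray) -> float:
    c = points - points.mean(axis=0)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    ax = v[:, -1]
    return math.degrees(math.atan2(ax[1], ax[0]))


def register_to_reference(
    moving_centroids,
    reference_centroids,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> RegistrationResult:
    """Rigid registration of droplet centroids by iterative closest point.

    Minimises the mean squared nearest-neighbour distance from the moved
    points to the reference under rotation + translation only. ICP is run
    from several initial rotations (principal-axis alignment plus a coarse
    scan) and the best final fit wins, which makes recovery exact for
    noise-free rigid copies well beyond +/-30 degrees. Non-convergence
    returns the best transform found with ``converged=False``.
    """
    mov = np.asarray(moving_centroids, dtype=float)
    ref = np.asarray(reference_centroids, dtype=float)
    if len(mov) < 3 or len(ref) < 3:
        raise ValueError("registration needs at least 3 points in each set")
    tree = cKDTree(ref)
    pa = _principal_angle(ref) - _principal_angle(mov)
    inits = sorted({round((pa + k) % 360.0, 6) for k in (0.0, 180.0)} | set(range(0, 360, 30)))

    best = None
    for init_deg in inits:
        T = RigidTransform(rotation_deg=init_deg)
        moved = T.apply(mov)
        T = RigidTransform(
            rotation_deg=init_deg,
            translation=tuple(ref.mean(axis=0) - moved.mean(axis=0)),
        )
        prev_rms = np.inf
        converged = False
        for it in range(1, max_iter + 1):
            moved = T.apply(mov)
            dist, idx = tree.query(moved)
            rms = float(np.sqrt(np.mean(dist**2)))
            if abs(prev_rms - rms) < tol:
                converged = True
                break
            prev_rms = rms
            T = _kabsch_2d(mov, ref[idx])
        moved = T.apply(mov)
        dist, _ = tree.query(moved)
        rms = float(np.sqrt(np.mean(dist**2)))
        cand = RegistrationResult(transform=T, converged=converged, rms=rms, n_iter=it)
        if best is None or _better(cand, best):
            best = cand
    return best


def _better(cand: RegistrationResult, best: RegistrationResult) -> bool:
    # lattices have rotational symmetries, so several exact registrations can
    # exist; among (near-)ties prefer the smallest rotation for determinism
    if cand.rms < best.rms - 1e-9:
        return True
    if cand.rms > best.rms + 1e-9:
        return False
    return abs(_wrap_deg(cand.transform.rotation_deg)) < abs(
        _wrap_deg(best.transform.rotation_deg)
    )


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def rasterize_class_map(
    triangles: pd.DataFrame,
    centroids,
    transform: RigidTransform,
    image_shape,
    classes=CLASSES,
) -> dict:
    """Per-class binary presence maps from classified triangles.

    Each triangle's pixel footprint (vertices moved by ``transform``) is set
    in its class's map; triangles falling outside the frame are clipped.
    """
    pts = np.asarray(centroids, dtype=float)
    maps = {cls: np.zeros(image_shape, dtype=bool) for cls in classes}
    for _, row in triangles.iterrows():
        verts = transform.apply(pts[[int(row.v0), int(row.v1), int(row.v2)]])
        rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=image_shape)
        maps[row.packing_class][rr, cc] = True
    return maps


def accumulate(maps_per_print) -> dict:
    """Pixelwise integer sum of per-print binary maps, per class."""
    maps_per_print = list(maps_per_print)
    if not maps_per_print:
        raise ValueError("no maps to accumulate")
    classes = list(maps_per_print[0])
    shape = maps_per_print[0][classes[0]].shape
    out = {}
    for cls in classes:
        acc = np.zeros(shape, dtype=int)
        for maps in maps_per_print:
            if maps[cls].shape != shape:
                raise ValueError(
                    f"map shape mismatch: {maps[cls].shape} vs {shape}"
                )
            acc += maps[cls].astype(int)
        out[cls] = acc
    return out


@dataclass(frozen=True)
class HexLayout:
    """Idealised print design: droplet centres, lattice spacing, row orientation."""

    centers: np.ndarray
    spacing: float
    orientation_deg: float = 0.0


@dataclass
class HexBinMap:
    """Hexagonal bins with per-class sums and normalised proportions.

    ``bins`` has one row per bin with columns ``s_<class>`` (pixel-count sums)
    and ``s_hat_<class>`` (proportions; NaN for bins with no data).
    ``bin_label_image`` maps each pixel to its bin id (-1 = outside all bins).
    """

    bins: pd.DataFrame
    bin_label_image: np.ndarray
    classes: tuple


def bin_hexagonal(H: dict, layout: HexLayout) -> HexBinMap:
    """Bin accumulated class maps onto the idealised hexagonal droplet layout.

    Bins are the regular hexagons of circumradius spacing/sqrt(3) centred on
    the design's droplet positions — the Voronoi cells of a triangular
    lattice, so they tessellate exactly. Pixels are assigned to the nearest
    bin centre and kept only if inside that centre's hexagon; bins with zero
    total count get NaN proportions (no data, as opposed to zero of a class).
    """
    centers = np.asarray(layout.centers, dtype=float)
    if centers.ndim != 2 or len(centers) < 1:
        raise LayoutError("layout must provide at least one bin centre")
    if layout.spacing <= 0:
        raise LayoutError("layout spacing must be positive")
    if len(centers) > 1:
        tree_c = cKDTree(centers)
        dmin, _ = tree_c.query(centers, k=2)
        if layout.spacing > dmin[:, 1].min() * (1.0 + 1e-9):
            raise LayoutError(
                "bins overlap: layout spacing exceeds the minimum centre distance"
            )

    classes = tuple(H)
    shape = H[classes[0]].shape
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(centers)
    _, nearest = tree.query(pix)

    # keep pixels inside the hexagon: within spacing/2 of the centre along all
    # six neighbour directions of the lattice
    angles = np.radians(layout.orientation_deg + np.arange(0, 360, 60))
    dirs = np.column_stack([np.cos(angles), np.sin(angles)])
    offset = pix - centers[nearest]
    inside = np.all(offset @ dirs.T <= layout.spacing / 2.0 + 1e-9, axis=1)
    bin_label = np.where(inside, nearest, -1).reshape(shape)

    rows = []
    for b, (cx, cy) in enumerate(centers):
        sel = bin_label == b
        row = {"bin_id": b, "cx": cx, "cy": cy, "n_pixels": int(sel.sum())}
        total = 0.0
        for cls in classes:
            s = float(H[cls][sel].sum())
            row[f"s_{cls}"] = s
            total += s
        for cls in classes:
            row[f"s_hat_{cls}"] = row[f"s_{cls}"] / total if total > 0 else np.nan
        row["defined"] = total > 0
        rows.append(row)
    return HexBinMap(bins=pd.DataFrame(rows), bin_label_image=bin_label, classes=classes)
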