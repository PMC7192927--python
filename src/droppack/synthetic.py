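"""Synthetic droplet-network images with exact ground truth.

Emulates the data the packing analysis consumes: membrane-fluorescence images
of the first layer of a printed droplet network (membranes bright, droplet
interiors and oil dark), droplet-pair images at a prescribed contact angle,
and noisy composition->angle measurement tables drawn from a known plane.

The fully packed first layer is idealised as the Voronoi partition of the
droplet centres clipped to the union of equal discs: touching droplets share
straight bright edges (the bilayers), non-touching droplets appear as
isolated bright circles (their monolayer rims). That idealisation has an
analytic ground truth — every rendered region is known exactly — which is
what makes the downstream segmentation and classification testable.

Every generator is a pure function of its arguments and an integer seed; the
random stream of each operation is derived from the seed by stable hashing,
so adding one generator call never shifts the randomness of another.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter
from scipy.spatial import ConvexHull, cKDTree

from .errors import CapacityError, GeometryError, ImageSizeError
from .geometry import RegressionPlane, DropletPair, pair_distance_from_angle

__all__ = [
    "LatticeSpec",
    "Lattice",
    "SyntheticNetwork",
    "gen_lattice",
    "render_membrane_image",
    "synthesize_network",
    "inject_inclusions",
    "add_excess_droplets",
    "gen_pair_image",
    "gen_theta_dataset",
    "write_network",
    "load_image",
]

LATTICE_TYPES = ("hexagonal", "square", "amorphous", "sparse", "mixed")

#: Sparse lattices inflate the spacing to at least this multiple of the
#: droplet diameter so that no two discs touch.
SPARSE_SPACING_FACTOR = 2.2

#: Jitter applied to the rim sites of a "mixed" lattice, as a fraction of the
#: spacing, when the spec does not set jitter_sigma itself.
MIXED_RIM_JITTER_FRACTION = 0.25
MIXED_RIM_DEPTH = 2  # lattice rows/columns counted as rim


def _rng(seed: int, op: str) -> np.random.Generator:
    """Per-operation random stream derived from the user seed by stable hashing."""
    tag = zlib.crc32(op.encode("ascii")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass(frozen=True)
class LatticeSpec:
    """Design of a first-layer droplet lattice.

    ``spacing`` is the centre-to-centre distance in pixels; ``jitter_sigma``
    the SD of isotropic Gaussian positional noise (amorphous lattices).
    """

    lattice_type: str = "hexagonal"
    nx: int = 10
    ny: int = 10
    spacing: float = 45.0
    droplet_radius: float = 25.0
    jitter_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.lattice_type not in LATTICE_TYPES:
            raise ValueError(f"lattice_type must be one of {LATTICE_TYPES}")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("nx and ny must both be >= 2")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")


_HEX_DIRECTIONS = np.array(
    [[np.cos(np.radians(a)), np.sin(np.radians(a))] for a in range(0, 360, 60)]
)
_SQUARE_DIRECTIONS = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])


@dataclass(frozen=True)
class Lattice:
    """Generated droplet centres plus the design metadata downstream stages need."""

    centroids: np.ndarray  # (n, 2) x, y
    site_class: np.ndarray  # per-site label: "core" or "rim"
    spacing: float
    droplet_radius: float
    lattice_type: str
    neighbor_directions: np.ndarray  # unit-step offsets to expected neighbours
    spec: LatticeSpec


def gen_lattice(spec: LatticeSpec) -> Lattice:
    """Generate droplet centres for the requested lattice type.

    hexagonal: triangular lattice, rows offset by spacing/2, row pitch
    spacing*sqrt(3)/2. square: rectangular grid. amorphous: hexagonal plus
    Gaussian jitter of SD ``jitter_sigma``. sparse: hexagonal with the
    spacing inflated so neighbouring discs cannot touch. mixed: hexagonal
    core with a jittered (amorphous) rim, plus a per-site region label.
    """
    s = spec.spacing
    if spec.lattice_type == "sparse":
        s = max(s, SPARSE_SPACING_FACTOR * 2.0 * spec.droplet_radius)

    pts = []
    ij = []
    if spec.lattice_type == "square":
        for j in range(spec.ny):
            for i in range(spec.nx):
                pts.append((i * s, j * s))
                ij.append((i, j))
        directions = _SQUARE_DIRECTIONS * s
    else:
        pitch = s * np.sqrt(3.0) / 2.0
        for j in range(spec.ny):
            xoff = (j % 2) * s / 2.0
            for i in range(spec.nx):
                pts.append((i * s + xoff, j * pitch))
                ij.append((i, j))
        directions = _HEX_DIRECTIONS * s
    pts = np.asarray(pts, dtype=float)
    ij = np.asarray(ij)

    site_class = np.full(len(pts), "core", dtype=object)
    if spec.lattice_type == "amorphous" and spec.jitter_sigma > 0:
        rng = _rng(spec.seed, "gen_lattice")
        pts = pts + rng.normal(0.0, spec.jitter_sigma, size=pts.shape)
    elif spec.lattice_type == "mixed":
        d = MIXED_RIM_DEPTH
        rim = (
            (ij[:, 0] < d)
            | (ij[:, 0] >= spec.nx - d)
            | (ij[:, 1] < d)
            | (ij[:, 1] >= spec.ny - d)
        )
        site_class[rim] = "rim"
        sigma = spec.jitter_sigma if spec.jitter_sigma > 0 else MIXED_RIM_JITTER_FRACTION * s
        rng = _rng(spec.seed, "gen_lattice")
        jitter = rng.normal(0.0, sigma, size=pts.shape)
        pts = pts + np.where(rim[:, None], jitter, 0.0)

    return Lattice(
        centroids=pts,
        site_class=np.asarray(site_class),
        spacing=s,
        droplet_radius=spec.droplet_radius,
        lattice_type=spec.lattice_type,
        neighbor_directions=directions,
        spec=spec,
    )


@dataclass
class SyntheticNetwork:
    """A rendered first-layer network with exact ground truth.

    ``ground_truth_labels`` is the unblurred partition (0 = oil/background,
    i = region of the i-th active centroid). ``inclusion_mask`` marks pixels
    of the design footprint vacated by removed droplets (trapped oil).
    """

    centroids: np.ndarray  # active droplet centres, image coordinates (x, y)
    ground_truth_labels: np.ndarray
    membrane_image: np.ndarray
    inclusion_mask: np.ndarray
    n_design: int
    n_excess: int = 0
    droplet_radius: float = 25.0
    ridge_width: float = 3.0
    blur_sigma: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0
    spacing: float | None = None
    neighbor_directions: np.ndarray | None = None
    design_centroids: np.ndarray | None = None  # original design, image coords
    best_effort: bool = False
    notes: list = field(default_factory=list)

    @property
    def shape(self):
        return self.membrane_image.shape

    def region_areas(self) -> np.ndarray:
        """Ground-truth pixel area of each droplet region, indexed by centroid."""
        counts = np.bincount(
            self.ground_truth_labels.ravel(), minlength=len(self.centroids) + 1
        )
        return counts[1:].astype(float)


def _render(
    centroids: np.ndarray,
    droplet_radius: float,
    ridge_width: float,
    blur_sigma: float,
    noise_sigma: float,
    seed: int,
    shape: tuple[int, int],
    coverage_centroids: np.ndarray | None = None,
):
    """Rasterise the clipped-Voronoi partition and its bright membrane ridges."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    tree = cKDTree(centroids)
    k = min(2, len(centroids))
    dist, idx = tree.query(pix, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    d1 = dist[:, 0]
    labels = np.where(d1 <= droplet_radius, idx[:, 0] + 1, 0).reshape(h, w)

    half = ridge_width / 2.0
    rim = np.abs(d1 - droplet_radius) <= half
    if k == 2:
        between = (dist[:, 1] - d1 <= ridge_width) & (d1 <= droplet_radius)
        membrane = (rim | between).reshape(h, w)
    else:
        membrane = rim.reshape(h, w)

    image = membrane.astype(float)
    if blur_sigma > 0:
        image = gaussian_filter(image, blur_sigma)
    if noise_sigma > 0:
        rng = _rng(seed, "render_membrane_image")
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)

    if coverage_centroids is not None and len(coverage_centroids):
        cov_tree = cKDTree(coverage_centroids)
        dcov, _ = cov_tree.query(pix, k=1)
        coverage = (dcov <= droplet_radius).reshape(h, w)
        inclusion_mask = coverage & (labels == 0)
    else:
        inclusion_mask = np.zeros((h, w), dtype=bool)
    return labels, image, inclusion_mask


def _frame(centroids: np.ndarray, droplet_radius: float, pad: float):
    lo = centroids.min(axis=0) - droplet_radius - pad
    hi = centroids.max(axis=0) + droplet_radius + pad
    offset = -lo
    w = int(np.ceil(hi[0] - lo[0])) + 1
    h = int(np.ceil(hi[1] - lo[1])) + 1
    return offset, (h, w)


def render_membrane_image(
    centroids,
    droplet_radius: float = 25.0,
    ridge_width: float = 3.0,
    blur_sigma: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    spacing: float | None = None,
    neighbor_directions=None,
) -> SyntheticNetwork:
    """Render droplet centres into a membrane-fluorescence image with ground truth.

    Regions are the Voronoi cells of the centres clipped to discs of
    ``droplet_radius``; region boundaries (bilayers between touching droplets,
    monolayer rims elsewhere) are drawn as bright ridges of ``ridge_width``,
    then Gaussian-blurred and corrupted with additive Gaussian noise.
    """
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 centroids")
    pad = 2.0 * ridge_width + 3.0 * blur_sigma + 2.0
    offset, shape = _frame(pts, droplet_radius, pad)
    pts_px = pts + offset
    labels, image, inclusion = _render(
        pts_px, droplet_radius, ridge_width, blur_sigma, noise_sigma, seed, shape
    )
    return SyntheticNetwork(
        centroids=pts_px,
        ground_truth_labels=labels,
        membrane_image=image,
        inclusion_mask=inclusion,
        n_design=len(pts_px),
        droplet_radius=droplet_radius,
        ridge_width=ridge_width,
        blur_sigma=blur_sigma,
        noise_sigma=noise_sigma,
        seed=seed,
        spacing=spacing,
        neighbor_directions=(
            np.asarray(neighbor_directions) if neighbor_directions is not None else None
        ),
        design_centroids=pts_px.copy(),
    )


def synthesize_network(
    spec: LatticeSpec,
    ridge_width: float = 3.0,
    blur_sigma: float = 1.0,
    noise_sigma: float = 0.0,
    inclusion_fraction: float = 0.0,
    n_excess: int = 0,
) -> SyntheticNetwork:
    """Lattice generation, rendering and defect injection in one call."""
    lattice = gen_lattice(spec)
    net = render_membrane_image(
        lattice.centroids,
        droplet_radius=spec.droplet_radius,
        ridge_width=ridge_width,
        blur_sigma=blur_sigma,
        noise_sigma=noise_sigma,
        seed=spec.seed,
        spacing=lattice.spacing,
        neighbor_directions=lattice.neighbor_directions,
    )
    if inclusion_fraction > 0:
        net = inject_inclusions(net, inclusion_fraction, seed=spec.seed)
    if n_excess > 0:
        net = add_excess_droplets(net, n_excess, seed=spec.seed)
    return net


def _hull_clearance(points: np.ndarray) -> np.ndarray:
    """Distance of each point to the convex-hull boundary of the set."""
    hull = ConvexHull(points)
    verts = points[hull.vertices]
    segs = list(zip(verts, np.roll(verts, -1, axis=0)))
    d = np.full(len(points), np.inf)
    for a, b in segs:
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab)
        d = np.minimum(d, np.linalg.norm(points - proj, axis=1))
    return d


def _oil_fraction_ground_truth(net: SyntheticNetwork) -> float:
    inc = float(net.inclusion_mask.sum())
    drop = float((net.ground_truth_labels > 0).sum())
    total = inc + drop
    return inc / total if total > 0 else 0.0


def inject_inclusions(
    net: SyntheticNetwork, target_fraction: float, seed: int = 0
) -> SyntheticNetwork:
    """Trap oil pockets by removing interior droplets until the inclusion-area
    fraction is within +/-20% of ``target_fraction``.

    Re-rendering without a removed site lets the neighbouring discs bulge into
    the vacancy, so the pocket is a concave region (convexity < 0.9) — the
    morphology the droplet/inclusion classifier keys on. If the target cannot
    be reached the closest achievable network is returned with
    ``best_effort=True``.
    """
    if not 0.0 <= target_fraction < 0.3:
        raise ValueError("target_fraction must lie in [0, 0.3)")
    if target_fraction == 0.0:
        return replace(net)

    design = net.design_centroids if net.design_centroids is not None else net.centroids
    tree = cKDTree(net.centroids)
    nn_dist, _ = tree.query(net.centroids, k=2)
    pitch = float(np.median(nn_dist[:, 1]))
    # interior = clear of the hull boundary by about one lattice pitch, so a
    # vacancy stays enclosed by surviving droplets (hull *vertices* alone miss
    # edge sites lying on straight hull edges)
    clearance = _hull_clearance(net.centroids)
    interior = np.nonzero(clearance >= 0.9 * pitch)[0]
    if len(interior) == 0:
        out = replace(net, best_effort=True)
        out.notes = list(net.notes) + ["no interior droplets to remove"]
        return out
    rng = _rng(seed, "inject_inclusions")
    # remove adjacent pairs where possible: merged vacancies are elongated and
    # concave, i.e. morphologically distinguishable from droplets downstream
    interior_set = set(int(i) for i in interior)
    order_list: list[int] = []
    used: set[int] = set()
    for site in rng.permutation(interior):
        site = int(site)
        if site in used:
            continue
        order_list.append(site)
        used.add(site)
        nbrs = [
            int(j)
            for j in tree.query_ball_point(net.centroids[site], 1.3 * pitch)
            if int(j) in interior_set and int(j) not in used and int(j) != site
        ]
        if nbrs:
            mate = int(rng.choice(nbrs))
            order_list.append(mate)
            used.add(mate)
    order = np.asarray(order_list, dtype=int)

    def attempt(k: int) -> SyntheticNetwork:
        keep = np.setdiff1d(np.arange(len(net.centroids)), order[:k])
        centroids = net.centroids[keep]
        labels, image, inclusion = _render(
            centroids,
            net.droplet_radius,
            net.ridge_width,
            net.blur_sigma,
            net.noise_sigma,
            net.seed,
            net.shape,
            coverage_centroids=design,
        )
        return replace(
            net,
            centroids=centroids,
            ground_truth_labels=labels,
            membrane_image=image,
            inclusion_mask=inclusion,
        )

    lo_band = 0.8 * target_fraction
    hi_band = 1.2 * target_fraction
    # achieved fraction is monotone in the removal count along the fixed order:
    # grow k geometrically, then bisect to the first k reaching the target
    k = 1
    best = attempt(k)
    while _oil_fraction_ground_truth(best) < target_fraction and k < len(order):
        k = min(2 * k, len(order))
        best = attempt(k)
    if _oil_fraction_ground_truth(best) < target_fraction:  # exhausted interior
        f = _oil_fraction_ground_truth(best)
        if f < lo_band:
            best.best_effort = True
            best.notes = list(net.notes) + [
                f"inclusion target {target_fraction:g} unreachable; achieved {f:.4f}"
            ]
        return best
    lo, hi = k // 2, k
    while hi - lo > 1:
        mid = (lo + hi) // 2
        cand = attempt(mid)
        if _oil_fraction_ground_truth(cand) < target_fraction:
            lo = mid
        else:
            hi, best = mid, cand
    f = _oil_fraction_ground_truth(best)
    if f > hi_band:  # one removal overshoots the band; step back if that helps
        cand = attempt(hi - 1)
        if abs(_oil_fraction_ground_truth(cand) - target_fraction) < abs(f - target_fraction):
            best, f = cand, _oil_fraction_ground_truth(cand)
        if not lo_band <= f <= hi_band:
            best.best_effort = True
            best.notes = list(net.notes) + [
                f"inclusion granularity overshoot: achieved {f:.4f} for target {target_fraction:g}"
            ]
    return best


def add_excess_droplets(net: SyntheticNetwork, n_extra: int, seed: int = 0) -> SyntheticNetwork:
    """Append droplets that "fell from the upper layers" at vacant sites
    adjacent to the network boundary. ``n_design`` is left unchanged.
    """
    if n_extra < 0:
        raise ValueError("n_extra must be >= 0")
    if n_extra == 0:
        return replace(net)
    if net.spacing is None or net.neighbor_directions is None:
        raise ValueError("network carries no lattice metadata; cannot place excess droplets")

    s = net.spacing
    cand = (net.centroids[:, None, :] + net.neighbor_directions[None, :, :]).reshape(-1, 2)
    tree = cKDTree(net.centroids)
    dmin, _ = tree.query(cand, k=1)
    vacant = cand[dmin >= 0.95 * s]
    # dedupe near-coincident candidates proposed by several neighbours
    keyed = {}
    for p in vacant:
        keyed.setdefault((round(p[0] / 2.0), round(p[1] / 2.0)), p)
    vacant = np.asarray(list(keyed.values()))
    if len(vacant) < n_extra:
        raise CapacityError(
            f"only {len(vacant)} vacant boundary-adjacent sites for {n_extra} extra droplets"
        )
    rng = _rng(seed, "add_excess_droplets")
    pick = rng.choice(len(vacant), size=n_extra, replace=False)
    centroids = np.vstack([net.centroids, vacant[pick]])

    design = net.design_centroids if net.design_centroids is not None else net.centroids
    coverage = np.vstack([design, vacant[pick]])
    # fallen droplets sit outside the original footprint: re-frame so they fit
    pad = 2.0 * net.ridge_width + 3.0 * net.blur_sigma + 2.0
    shift, shape = _frame(centroids, net.droplet_radius, pad)
    centroids = centroids + shift
    coverage = coverage + shift
    labels, image, inclusion = _render(
        centroids,
        net.droplet_radius,
        net.ridge_width,
        net.blur_sigma,
        net.noise_sigma,
        net.seed,
        shape,
        coverage_centroids=coverage,
    )
    return replace(
        net,
        centroids=centroids,
        design_centroids=design + shift,
        ground_truth_labels=labels,
        membrane_image=image,
        inclusion_mask=inclusion,
        n_excess=net.n_excess + n_extra,
    )


def gen_pair_image(
    R1: float,
    R2: float,
    theta: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
    ridge_width: float = 3.0,
    blur_sigma: float = 1.0,
    shape: tuple[int, int] | None = None,
):
    """Render a droplet pair at a prescribed contact angle.

    The centre distance is derived by inverting the pair-angle relation, the
    two truncated circles are drawn as bright outlines and the bilayer as a
    bright chord. Returns ``(image, DropletPair)`` where the second element
    carries the exact (R1, R2, L, theta) ground truth.
    """
    if R1 < 10 or R2 < 10:
        raise GeometryError("radii must be >= 10 px for a resolvable rim")
    if not 0.0 <= theta < 90.0:
        raise GeometryError("theta must lie in [0, 90) degrees")
    L = pair_distance_from_angle(R1, R2, theta)
    truth = DropletPair(R1=R1, R2=R2, L=L, theta_dib=theta)

    pad = 2.0 * ridge_width + 3.0 * blur_sigma + 4.0
    w_need = int(np.ceil(R1 + L + R2 + 2 * pad)) + 1
    h_need = int(np.ceil(2 * max(R1, R2) + 2 * pad)) + 1
    if shape is None:
        h, w = h_need, w_need
    else:
        h, w = shape
        if h < h_need or w < w_need:
            raise ImageSizeError(
                f"shape {shape} too small; pair needs at least ({h_need}, {w_need})"
            )
    c1 = np.array([pad + R1, h / 2.0])
    c2 = c1 + np.array([L, 0.0])

    yy, xx = np.mgrid[0:h, 0:w]
    d1 = np.hypot(xx - c1[0], yy - c1[1])
    d2 = np.hypot(xx - c2[0], yy - c2[1])
    # signed distance along the axis from the bilayer (radical) plane
    a = (L * L + R1 * R1 - R2 * R2) / (2.0 * L)
    xline = (xx - c1[0]) - a

    half = ridge_width / 2.0
    rim1 = (np.abs(d1 - R1) <= half) & (xline <= half)
    rim2 = (np.abs(d2 - R2) <= half) & (xline >= -half)
    chord = (np.abs(xline) <= half) & (d1 <= R1 + half) & (d2 <= R2 + half)
    image = (rim1 | rim2 | chord).astype(float)
    if blur_sigma > 0:
        image = gaussian_filter(image, blur_sigma)
    if noise_sigma > 0:
        rng = _rng(seed, "gen_pair_image")
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    return image, truth


def gen_theta_dataset(
    plane: RegressionPlane,
    design,
    noise_sigma: float = 1.0,
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Noisy contact-angle measurements at the given (phi_SIL, x_POPC) design points.

    theta = plane prediction + iid Gaussian noise; long-format table with one
    row per replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    design = np.asarray(design, dtype=float).reshape(-1, 2)
    rng = _rng(seed, "gen_theta_dataset")
    rows = []
    for rep in range(n_reps):
        for phi, x in design:
            mu = plane.intercept + plane.slope_phi * phi + plane.slope_x * x
            rows.append(
                {
                    "phi_SIL": phi,
                    "x_POPC": x,
                    "rep": rep,
                    "theta_deg": mu + rng.normal(0.0, noise_sigma),
                }
            )
    return pd.DataFrame(rows)


def write_network(net: SyntheticNetwork, outdir) -> dict:
    """Write image/labels as 16-bit TIFF, ground truth as CSV, spec as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img = np.clip(net.membrane_image, 0.0, None)
    peak = img.max() if img.max() > 0 else 1.0
    tifffile.imwrite(outdir / "membrane.tif", (img / peak * 65535).astype(np.uint16))
    tifffile.imwrite(outdir / "labels.tif", net.ground_truth_labels.astype(np.uint16))
    truth = pd.DataFrame(
        {
            "x": net.centroids[:, 0],
            "y": net.centroids[:, 1],
            "radius": net.droplet_radius,
        }
    )
    truth.to_csv(outdir / "truth.csv", index=False)
    meta = {
        "n_design": net.n_design,
        "n_excess": net.n_excess,
        "n_active": int(len(net.centroids)),
        "droplet_radius": net.droplet_radius,
        "ridge_width": net.ridge_width,
        "blur_sigma": net.blur_sigma,
        "noise_sigma": net.noise_sigma,
        "seed": net.seed,
        "spacing": net.spacing,
        "best_effort": net.best_effort,
        "notes": list(net.notes),
    }
    (outdir / "network.json").write_text(json.dumps(meta, indent=2))
    return meta


def load_image(path) -> np.ndarray:
    """Load a grayscale TIFF/PNG as float in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:  # collapse RGB(A) to luminance
        img = img[..., :3].mean(axis=-1)
    peak = img.max()
    return img / peak if peak > 0 else img
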