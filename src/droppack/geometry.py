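"""Closed-form geometry of droplet interface bilayers (DIBs).

A DIB forms when two lipid-monolayer-coated aqueous droplets in oil adhere
and build a flat bilayer at their contact. The equilibrium contact angle
``theta_DIB`` — measured where the two spherical droplet surfaces meet the
bilayer plane — encodes the monolayer/bilayer tension balance and is the
single control parameter for how hundreds of printed droplets pack.

This module collects the closed-form relations used throughout the package:

* the pair contact angle from the two radii and the centre distance,
* the surface contact angle of a droplet sitting on a substrate,
* the linear regression plane ``theta_DIB(phi_SIL, x_POPC)`` mapping oil and
  lipid composition to contact angle,
* volume-conserving deformation of an equal pair (truncated-sphere radius,
  centre-to-centre shrinkage, bilayer disc radius),
* the Young-balance adhesion energy,
* the geometric critical angle: half the regular-tetrahedron dihedral angle,
  the smallest contact angle at which four tetrahedrally arranged droplets
  squeeze out the interstitial oil.

All angles cross the API in degrees; radians appear only inside functions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import GeometryError, NonPhysicalAngleWarning, SingularFitError

__all__ = [
    "DropletPair",
    "SurfaceContact",
    "RegressionPlane",
    "EquilibriumPairGeometry",
    "AdhesionEnergy",
    "PUBLISHED_PLANE",
    "N_T_FIRST_LAYER",
    "contact_angle_from_pair",
    "pair_distance_from_angle",
    "surface_contact_angle",
    "fit_theta_plane",
    "predict_theta",
    "published_plane",
    "tetrahedron_dihedral_angle",
    "critical_contact_angle",
    "equilibrium_pair_geometry",
    "adhesion_energy",
    "sphere_volume_pL",
    "read_theta_table",
    "write_theta_table",
]

#: Expected droplet count in the first layer of the standard 7 x 8 x 4 print,
#: which settles into an 8 x 9 bottom layer.
N_T_FIRST_LAYER = 72

THETA_TABLE_COLUMNS = ("phi_SIL", "x_POPC", "theta_deg")


@dataclass(frozen=True)
class DropletPair:
    """A two-droplet DIB system: radii, centre distance, contact angle (deg)."""

    R1: float
    R2: float
    L: float
    theta_dib: float

    def __post_init__(self):
        if self.R1 <= 0 or self.R2 <= 0:
            raise GeometryError("droplet radii must be positive")
        if not 0.0 <= self.L <= self.R1 + self.R2:
            raise GeometryError(
                f"centre distance L={self.L:g} outside [0, R1+R2] for a DIB"
            )
        if not 0.0 <= self.theta_dib < 90.0:
            raise GeometryError(
                f"theta_dib={self.theta_dib:g} deg outside the physical DIB range [0, 90)"
            )


@dataclass(frozen=True)
class SurfaceContact:
    """A droplet adhering to a substrate: cap radius, surface-bilayer patch radius."""

    R_a: float
    R_b: float
    theta_surface: float

    def __post_init__(self):
        if not 0.0 <= self.R_b <= self.R_a:
            raise GeometryError("surface bilayer radius must satisfy 0 <= R_b <= R_a")


@dataclass(frozen=True)
class RegressionPlane:
    """Linear model theta_DIB = intercept + slope_phi * phi_SIL + slope_x * x_POPC.

    ``published=True`` marks the instance that stores the published
    coefficients verbatim (rounded to three decimals in their original
    normalisation); predictions from it are accurate to roughly +/- 1.5 deg
    relative to values quoted from the unrounded fit.
    """

    slope_phi: float
    slope_x: float
    intercept: float
    r_squared: float | None = None
    published: bool = False

    def predict(self, phi_sil, x_popc):
        return predict_theta(self, phi_sil, x_popc)


#: The printed composition->angle plane:
#: theta = (0.930 phi_SIL + 0.368 x_POPC - 0.238) / 0.009, in degrees.
PUBLISHED_PLANE = RegressionPlane(
    slope_phi=0.930 / 0.009,
    slope_x=0.368 / 0.009,
    intercept=-0.238 / 0.009,
    r_squared=0.99,
    published=True,
)


def published_plane() -> RegressionPlane:
    """Return the published composition->angle regression plane."""
    return replace(PUBLISHED_PLANE)


@dataclass(frozen=True)
class EquilibriumPairGeometry:
    """Volume-conserving deformation of an equal droplet pair at contact angle theta.

    Each droplet starts as a sphere of radius ``R0`` and, upon forming a flat
    bilayer, becomes a sphere of radius ``R_theta`` truncated by the bilayer
    plane. ``L_theta = 2 R_theta cos(theta)`` is the equilibrium centre
    distance and ``r_bilayer = R_theta sin(theta)`` the bilayer disc radius.
    """

    R0: float
    theta: float
    R_theta: float
    L_theta: float
    r_bilayer: float


@dataclass(frozen=True)
class AdhesionEnergy:
    """Young balance at a DIB: gamma_b = 2 gamma_m cos(theta).

    ``delta_F = 2 gamma_m (1 - cos theta)`` is the free-energy gain per unit
    bilayer area on replacing two monolayers by one bilayer (the work of
    adhesion), which grows monotonically with the contact angle.
    """

    gamma_m: float
    gamma_b: float
    delta_F: float


def contact_angle_from_pair(R1: float, R2: float, L: float) -> float:
    """Contact angle (degrees) of a droplet pair from radii and centre distance.

    Uses ``2 theta = arccos((L^2 - R1^2 - R2^2) / (2 R1 R2))``: the angle at
    which the two circles of radii ``R1``, ``R2`` with centres ``L`` apart
    intersect. Tangent spheres (``L = R1 + R2``) give 0 deg.
    """
    if R1 <= 0 or R2 <= 0:
        raise GeometryError("droplet radii must be positive")
    if L <= 0:
        raise GeometryError("centre distance must be positive")
    arg = (L * L - R1 * R1 - R2 * R2) / (2.0 * R1 * R2)
    if not -1.0 <= arg <= 1.0:
        raise GeometryError(
            f"circles do not intersect: cos(2 theta) = {arg:.6g} outside [-1, 1]"
        )
    return 0.5 * math.degrees(math.acos(arg))


def pair_distance_from_angle(R1: float, R2: float, theta_deg: float) -> float:
    """Centre distance of a pair at a given contact angle (inverse of the above)."""
    if R1 <= 0 or R2 <= 0:
        raise GeometryError("droplet radii must be positive")
    if not 0.0 <= theta_deg < 90.0:
        raise GeometryError("theta must lie in [0, 90) degrees")
    c = math.cos(math.radians(2.0 * theta_deg))
    return math.sqrt(R1 * R1 + R2 * R2 + 2.0 * R1 * R2 * c)


def surface_contact_angle(R_b: float, R_a: float) -> float:
    """Contact angle (degrees) of a droplet on a surface: arcsin(R_b / R_a)."""
    if R_a <= 0:
        raise GeometryError("cap radius must be positive")
    if R_b < 0 or R_b > R_a:
        raise GeometryError("surface bilayer radius must satisfy 0 <= R_b <= R_a")
    return math.degrees(math.asin(R_b / R_a))


_DESIGN_NAMES = ("intercept", "phi_SIL", "x_POPC")


def fit_theta_plane(measurements) -> RegressionPlane:
    """Ordinary least-squares plane theta = b0 + b1*phi_SIL + b2*x_POPC.

    ``measurements`` is a sequence of ``(phi_SIL, x_POPC, theta_deg)`` triples
    or a DataFrame with those columns. Requires at least three non-collinear
    (phi, x) design points; a rank-deficient design raises
    :class:`SingularFitError` naming the deficient direction.
    """
    if isinstance(measurements, pd.DataFrame):
        arr = measurements.loc[:, list(THETA_TABLE_COLUMNS)].to_numpy(float)
    else:
        arr = np.asarray(measurements, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("expected (phi_SIL, x_POPC, theta_deg) triples")
    if arr.shape[0] < 3:
        raise SingularFitError("need at least 3 measurements to fit a plane")
    phi, x, theta = arr.T
    X = np.column_stack([np.ones_like(phi), phi, x])
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] <= s[0] * 1e-10:
        null = vt[-1]
        involved = [n for n, v in zip(_DESIGN_NAMES, null) if abs(v) > 1e-8]
        raise SingularFitError(
            "rank-deficient design: (phi_SIL, x_POPC) points are collinear "
            f"along the direction spanned by {involved}"
        )
    beta, *_ = np.linalg.lstsq(X, theta, rcond=None)
    resid = theta - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((theta - theta.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return RegressionPlane(
        slope_phi=float(beta[1]),
        slope_x=float(beta[2]),
        intercept=float(beta[0]),
        r_squared=r2,
    )


def predict_theta(plane: RegressionPlane, phi_sil, x_popc):
    """Evaluate the plane. Values outside [0, 90) deg are returned but flagged.

    Out-of-range predictions signal extrapolation beyond physical DIBs and
    raise :class:`NonPhysicalAngleWarning` rather than being clamped.
    """
    theta = plane.intercept + plane.slope_phi * np.asarray(phi_sil) + plane.slope_x * np.asarray(x_popc)
    if np.any(theta < 0.0) or np.any(theta >= 90.0):
        warnings.warn(
            "predicted theta_DIB outside the physical range [0, 90) degrees",
            NonPhysicalAngleWarning,
            stacklevel=2,
        )
    return float(theta) if np.ndim(theta) == 0 else theta


def tetrahedron_dihedral_angle() -> float:
    """Dihedral angle of the regular tetrahedron, arccos(1/3) = 70.5288... deg."""
    return math.degrees(math.acos(1.0 / 3.0))


def critical_contact_angle() -> float:
    """Critical contact angle theta_c = 35.2644... deg (prints as 35.3, 3 s.f.).

    Half the regular-tetrahedron dihedral angle: the minimum pair contact
    angle at which four droplets whose centres sit at the vertices of a
    regular tetrahedron exclude the continuous oil phase they enclose.
    Equivalently the root of cos(2 theta) = 1/3.
    """
    return 0.5 * tetrahedron_dihedral_angle()


def _truncated_sphere_volume(R: float, theta_rad: float) -> float:
    # sphere of radius R minus the spherical cap cut off by the bilayer plane;
    # cap height h = R (1 - cos theta)
    h = R * (1.0 - math.cos(theta_rad))
    return (4.0 / 3.0) * math.pi * R**3 - math.pi * h * h * (3.0 * R - h) / 3.0


def equilibrium_pair_geometry(R0: float, theta_deg: float) -> EquilibriumPairGeometry:
    """Deformed geometry of an equal pair at contact angle theta, conserving volume.

    Solves for the truncated-sphere radius ``R(theta)`` such that the volume of
    a sphere of radius ``R`` truncated at cap height ``R (1 - cos theta)``
    equals the undeformed volume ``(4/3) pi R0^3`` (bracketed root on
    ``[R0, 2 R0]``, relative tolerance 1e-12). The centre distance
    ``L = 2 R cos theta`` shrinks monotonically with theta.
    """
    if R0 <= 0:
        raise GeometryError("R0 must be positive")
    if not 0.0 <= theta_deg < 90.0:
        raise GeometryError("theta must lie in [0, 90) degrees")
    t = math.radians(theta_deg)
    if theta_deg == 0.0:
        R = R0
    else:
        target = (4.0 / 3.0) * math.pi * R0**3
        R = brentq(
            lambda r: _truncated_sphere_volume(r, t) - target,
            R0,
            2.0 * R0,
            rtol=1e-14,
            xtol=1e-13 * R0,
        )
    return EquilibriumPairGeometry(
        R0=R0,
        theta=theta_deg,
        R_theta=R,
        L_theta=2.0 * R * math.cos(t),
        r_bilayer=R * math.sin(t),
    )


def adhesion_energy(gamma_m: float, theta_deg: float) -> AdhesionEnergy:
    """Young balance and work of adhesion at contact angle theta (degrees)."""
    if gamma_m <= 0:
        raise GeometryError("monolayer tension must be positive")
    if not 0.0 <= theta_deg < 90.0:
        raise GeometryError("theta must lie in [0, 90) degrees")
    c = math.cos(math.radians(theta_deg))
    return AdhesionEnergy(
        gamma_m=gamma_m,
        gamma_b=2.0 * gamma_m * c,
        delta_F=2.0 * gamma_m * (1.0 - c),
    )


def sphere_volume_pL(diameter_um: float) -> float:
    """Volume of a sphere of the given diameter (micrometres) in picolitres.

    A 100 um printed droplet occupies (pi/6) * 100^3 um^3 = 523.6 pL.
    """
    if diameter_um < 0:
        raise GeometryError("diameter must be non-negative")
    volume_um3 = (math.pi / 6.0) * diameter_um**3
    return volume_um3 * 1e-3  # 1 pL = 1000 um^3


def read_theta_table(path) -> pd.DataFrame:
    """Read a (phi_SIL, x_POPC, theta_deg) CSV with a one-line header."""
    df = pd.read_csv(path)
    missing = [c for c in THETA_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"theta table {path} is missing columns {missing}")
    return df


def write_theta_table(df: pd.DataFrame, path) -> None:
    """Write a (phi_SIL, x_POPC, theta_deg) table as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
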