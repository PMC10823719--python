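"""Planes in Hesse normal form and reflection geometry.

A candidate or reference midsagittal plane is ``{x : normal . x = offset}``
with a unit normal and the offset in mm.  The sign of the normal is
canonicalized (largest-magnitude component positive) so that planes can be
compared for equality and rankings are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Plane",
    "CollinearPointsError",
    "plane_from_points",
    "reflect_points",
    "signed_distance",
    "triangle_condition",
]

#: triangles with area below this (mm^2) are refused as plane supports
AREA_EPSILON = 1e-6


class CollinearPointsError(ValueError):
    """Raised when three points are too close to collinear to define a plane."""


def _canonical_normal(normal: np.ndarray) -> np.ndarray:
    """Flip the normal so its largest-magnitude component is positive.

    Ties are broken in axis order x, y, z.
    """
    a = np.abs(normal)
    # first index attaining the maximum (argmax is x,y,z ordered)
    lead = int(np.argmax(a))
    if normal[lead] < 0:
        return -normal
    return normal


@dataclass(frozen=True)
class Plane:
    """Oriented plane ``normal . x = offset`` with ``|normal| = 1``.

    Parameters
    ----------
    normal : (3,) array_like
        Plane normal; normalised and sign-canonicalised on construction.
    offset : float
        Signed distance of the plane from the origin along ``normal`` (mm).
    """

    normal: np.ndarray
    offset: float

    def __init__(self, normal, offset: float):
        n = np.asarray(normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm < 1e-12:
            raise ValueError("plane normal must be a nonzero finite vector")
        n = n / norm
        offset = float(offset) / 1.0
        canon = _canonical_normal(n)
        if not np.array_equal(canon, n):
            offset = -offset
            n = canon
        n.setflags(write=False)
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(offset))

    def signed_distance(self, points) -> np.ndarray | float:
        """Signed distance(s) from point(s) to the plane, in mm."""
        return signed_distance(points, self)

    def reflect(self, points) -> np.ndarray:
        """Mirror point(s) across the plane."""
        return reflect_points(points, self)

    def point_on_plane(self) -> np.ndarray:
        """The foot of the origin's perpendicular, a convenient anchor point."""
        return self.normal * self.offset

    def angle_to(self, other: "Plane") -> float:
        """Acute dihedral angle to another plane, in degrees."""
        c = abs(float(np.dot(self.normal, other.normal)))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def transformed(self, rotation, translation) -> "Plane":
        """Image of the plane under the rigid map ``x -> R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        n = R @ self.normal
        # point p on plane maps to R p + t; new offset is n' . (R p + t)
        p = self.point_on_plane()
        return Plane(n, float(n @ (R @ p + t)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n = self.normal
        return f"Plane(normal=({n[0]:+.4f}, {n[1]:+.4f}, {n[2]:+.4f}), offset={self.offset:.4f})"


def plane_from_points(p1, p2, p3, *, area_epsilon: float = AREA_EPSILON) -> Plane:
    """Plane through three points (mm), with canonical normal sign.

    Raises
    ------
    CollinearPointsError
        If the triangle spanned by the points has area below ``area_epsilon``
        (mm^2); such triplets give numerically unstable planes.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    cross = np.cross(p2 - p1, p3 - p1)
    area = 0.5 * np.linalg.norm(cross)
    if area < area_epsilon:
        raise CollinearPointsError(
            f"points are (near-)collinear: triangle area {area:.3g} mm^2 "
            f"< {area_epsilon:g} mm^2"
        )
    n = cross / np.linalg.norm(cross)
    return Plane(n, float(n @ p1))


def triangle_condition(p1, p2, p3) -> float:
    """Shape quality of a support triangle: area / longest_edge**2.

    Dimensionless in (0, sqrt(3)/4]; small values flag triplets whose plane
    is poorly conditioned (nearly collinear landmark triplets), without
    refusing them outright.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    area = 0.5 * np.linalg.norm(np.cross(p2 - p1, p3 - p1))
    longest = max(
        np.linalg.norm(p2 - p1), np.linalg.norm(p3 - p2), np.linalg.norm(p1 - p3)
    )
    if longest == 0.0:
        return 0.0
    return float(area / longest**2)


def signed_distance(points, plane: Plane):
    """``normal . x - offset`` for one point or an (n, 3) array of points."""
    pts = np.asarray(points, dtype=float)
    d = pts @ plane.normal - plane.offset
    if pts.ndim == 1:
        return float(d)
    return d


def reflect_points(points, plane: Plane) -> np.ndarray:
    """Householder reflection ``x' = x - 2 (n.x - offset) n`` across the plane."""
    pts = np.asarray(points, dtype=float)
    d = np.atleast_1d(pts @ plane.normal - plane.offset)
    out = pts - 2.0 * np.multiply.outer(d, plane.normal).reshape(pts.shape)
    return out
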