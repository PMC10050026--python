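"""Exact 3-D / 2-D geometric primitives underlying the pose simulation.

Coordinate conventions used throughout the package:

* ``x`` mediolateral, ``y`` anteroposterior, ``z`` longitudinal (cranial +).
* All lengths are millimetres; angles are degrees at API boundaries and
  radians internally.
* Points are plain ``numpy`` arrays — shape ``(3,)`` (or ``(n, 3)`` for
  clouds) in 3-D and ``(2,)`` holding ``(x, z)`` in the coronal plane.

The coronal ("frontal") projection discards the anteroposterior coordinate,
mimicking the orthographic geometry of a long-leg radiograph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .errors import (
    ConvergenceError,
    DegenerateGeometryError,
    GeometryError,
    InsufficientDataError,
)

_UNIT_TOL = 1e-9


@dataclass(frozen=True)
class Axis3:
    """A directed line in 3-D: a point on the line plus a unit direction."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        if origin.shape != (3,) or direction.shape != (3,):
            raise GeometryError("Axis3 requires 3-vectors for origin and direction")
        if not (np.all(np.isfinite(origin)) and np.all(np.isfinite(direction))):
            raise GeometryError("Axis3 components must be finite")
        if abs(np.linalg.norm(direction) - 1.0) > _UNIT_TOL:
            raise GeometryError(
                f"Axis3 direction must be unit length, got |d| = {np.linalg.norm(direction)!r}"
            )
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "direction", direction)

    @classmethod
    def through_points(cls, a: np.ndarray, b: np.ndarray) -> "Axis3":
        """Axis through ``a`` pointing toward ``b`` (normalized)."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        d = b - a
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise DegenerateGeometryError("cannot build an axis through coincident points")
        return cls(a, d / n)


def rotate_about_axis(points: np.ndarray, axis: Axis3, angle_deg: float) -> np.ndarray:
    """Rigidly rotate ``points`` about a (possibly off-origin) axis.

    Positive angles follow the right-hand rule about ``axis.direction``.
    Accepts a single point ``(3,)`` or a cloud ``(n, 3)``; returns the same
    shape. Pairwise distances are preserved to machine precision and points
    on the axis are fixed.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if abs(np.linalg.norm(axis.direction) - 1.0) > _UNIT_TOL:
        raise GeometryError("rotation axis direction must be unit length")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis.direction)
    out = rot.apply(pts - axis.origin) + axis.origin
    return out[0] if single else out


def project_coronal(p: np.ndarray) -> np.ndarray:
    """Orthographic coronal projection: keep ``(x, z)``, drop ``y``.

    Accepts ``(3,)`` or ``(n, 3)``; idempotent on already-projected input of
    shape ``(2,)`` / ``(n, 2)``.
    """
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] == 2:
        return arr.copy()
    return arr[..., [0, 2]]


def angle_2d(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle in degrees, in [0, 180], between two 2-vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-15 or nv < 1e-15:
        raise DegenerateGeometryError("angle_2d requires nonzero vectors")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def signed_point_line_distance_2d(
    p: np.ndarray,
    line_a: np.ndarray,
    line_b: np.ndarray,
    medial_sign: float = 1.0,
) -> float:
    """Signed perpendicular distance (mm) of ``p`` from the line ``a``–``b``.

    The raw sign is the 2-D cross product ``(b - a) x (p - a)``; with the line
    running cranial-to-caudal (``a`` proximal, ``b`` distal) and the package's
    "+x = lateral" canonical frame this is positive when ``p`` lies lateral to
    the line, i.e. when the line passes medial to ``p``. ``medial_sign``
    (±1) lets the caller encode side so that medial passage of the axis is
    reported positive for either leg.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(line_a, dtype=float)
    b = np.asarray(line_b, dtype=float)
    d = b - a
    n = np.linalg.norm(d)
    if n < 1e-12:
        raise DegenerateGeometryError("line points are coincident")
    cross = d[0] * (p - a)[1] - d[1] * (p - a)[0]
    # With a proximal and b distal (d_z < 0), cross > 0 <=> p lateral of the
    # line <=> the line passes medial to p.
    return float(medial_sign) * float(cross / n)


def _collinear(points: np.ndarray) -> bool:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] < 1e-8 * max(s[0], 1.0)


def _perp_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, d)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def point_axis_distance(points: np.ndarray, axis: Axis3) -> np.ndarray:
    """Radial distance of each point from an axis."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - axis.origin
    along = rel @ axis.direction
    radial = rel - np.outer(along, axis.direction)
    return np.linalg.norm(radial, axis=1)


def fit_cylinder_axis(points: np.ndarray, initial_axis: Axis3) -> Axis3:
    """Least-squares cylinder axis through a point cloud.

    Minimizes the sum of squared radial residuals (point-to-axis distance
    minus a fitted radius) over axis position (2 dof perpendicular to the
    initial direction), axis direction (2 dof) and radius, starting from
    ``initial_axis`` — in anatomical use, the epicondyle-centre chord, which
    lies well inside the basin of attraction.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 8:
        raise InsufficientDataError(
            f"cylinder fit needs >= 8 points, got {pts.shape[0]}"
        )
    if _collinear(pts):
        raise InsufficientDataError("cylinder fit requires a non-collinear cloud")

    d0 = initial_axis.direction
    e1, e2 = _perp_basis(d0)
    c0 = initial_axis.origin
    r0 = float(np.mean(point_axis_distance(pts, initial_axis)))
    if r0 < 1e-9:
        r0 = 1.0

    def unpack(x):
        s1, s2, a, b, r = x
        d = d0 + a * e1 + b * e2
        d = d / np.linalg.norm(d)
        c = c0 + s1 * e1 + s2 * e2
        return c, d, r

    def residuals(x):
        c, d, r = unpack(x)
        rel = pts - c
        along = rel @ d
        radial = rel - np.outer(along, d)
        return np.linalg.norm(radial, axis=1) - r

    sol = least_squares(
        residuals,
        x0=np.array([0.0, 0.0, 0.0, 0.0, r0]),
        method="lm",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    if not sol.success:
        raise ConvergenceError(f"cylinder fit did not converge: {sol.message}")
    c, d, _ = unpack(sol.x)
    if np.dot(d, d0) < 0:
        d = -d
    return Axis3(c, d)
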