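"""Anatomical coordinate frame: cylinder-fitted flexion axis + mechanical axis.

The frame mirrors how the study's coordinate system is established on each
bone model: the mediolateral x-axis is the axis of a best-fit cylinder
through the femoral epicondylar surface (the transepicondylar axis, the best
available approximation of the knee's flexion axis); the longitudinal z-axis
is the unit vector toward the femoral head centre lying in the plane spanned
by the x-axis and FHC − FNP (Gram–Schmidt of the femoral mechanical axis
against x); the anteroposterior y-axis completes the right-handed triad; the
origin is the femoral notch point, the best single-point approximation of
the knee centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientDataError
from .geometry import Axis3, fit_cylinder_axis
from .limb_model import LimbModel, reflect_to_lateral_x

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """Right-handed orthonormal anatomical frame (x lateral, y anterior, z cranial)."""

    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        axes = np.vstack([self.x_axis, self.y_axis, self.z_axis])
        if np.max(np.abs(axes @ axes.T - np.eye(3))) > 1e-8:
            raise DegenerateGeometryError("frame axes are not orthonormal")
        if np.max(np.abs(np.cross(self.x_axis, self.y_axis) - self.z_axis)) > 1e-8:
            raise DegenerateGeometryError("frame is not right-handed (x cross y != z)")

    @property
    def rotation(self) -> np.ndarray:
        """World-to-frame rotation matrix (rows are the frame axes)."""
        return np.vstack([self.x_axis, self.y_axis, self.z_axis])


def establish_frame(limb: LimbModel) -> Frame:
    """Recover the anatomical frame from a limb's landmarks.

    Expects a limb in the +x-lateral representation (right limbs natively;
    left limbs via :func:`limb_model.reflect_to_lateral_x`). Uses the
    epicondylar point cloud for the cylinder fit when available, otherwise
    falls back to the MEC–LEC chord.
    """
    lm = limb.landmarks
    chord = Axis3.through_points(lm["MEC"], lm["LEC"])
    chord = Axis3(0.5 * (lm["MEC"] + lm["LEC"]), chord.direction)
    if limb.epicondylar_cloud is not None and limb.epicondylar_cloud.shape[0] >= 8:
        try:
            axis = fit_cylinder_axis(limb.epicondylar_cloud, chord)
        except InsufficientDataError:
            axis = chord
    else:
        axis = chord
    x = axis.direction
    if np.dot(x, lm["LEC"] - lm["MEC"]) < 0:
        x = -x

    origin = lm["FNP"]
    fem = lm["FHC"] - origin
    if np.linalg.norm(fem) < 1e-9:
        raise DegenerateGeometryError("FHC coincides with FNP")
    z = fem - np.dot(fem, x) * x
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise DegenerateGeometryError("femoral mechanical axis is parallel to the flexion axis")
    z /= nz
    y = np.cross(z, x)
    return Frame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def to_neutral(limb: LimbModel, frame: Frame) -> LimbModel:
    """Rigidly transform a limb so ``frame`` maps onto the canonical axes.

    After the transform the frame origin (FNP) sits at the world origin and
    the frame axes coincide with the world x/y/z. Distances are preserved
    exactly (pure rotation + translation); applying the operation twice is a
    no-op because the re-established frame is then the identity.
    """
    R = frame.rotation
    out = limb.copy()
    for name, v in out.landmarks.items():
        out.landmarks[name] = R @ (v - frame.origin)
    if out.epicondylar_cloud is not None:
        out.epicondylar_cloud = (out.epicondylar_cloud - frame.origin) @ R.T
    out.canonical = True
    return out


def canonicalize(limb: LimbModel) -> LimbModel:
    """Bring any limb into its neutral side-canonical simulation frame.

    Left limbs are first reflected into the +x-lateral representation (side
    label preserved), then the anatomical frame is established and the limb
    is normalized to it. The result is what :mod:`limbproj.pose` expects.
    """
    work = reflect_to_lateral_x(limb)
    frame = establish_frame(work)
    return to_neutral(work, frame)
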