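"""Projected radiographic alignment measurements of a (posed) limb.

All four parameters are computed on the orthographic coronal projection
(the ``(x, z)`` coordinates), exactly as a reader would measure them on a
long-leg radiograph:

* **HKA** — medial angle between the projected femoral mechanical axis
  (FHC→FNP) and tibial mechanical axis (TKC→AJC); 180° = neutral, < 180°
  varus, > 180° valgus.
* **MPTA** — medial angle between the projected tibial plateau line
  (MTP–LTP) and the tibial mechanical axis.
* **mLDFA** — lateral angle between the projected femoral mechanical axis
  and the distal condylar line (MDC–LDC).
* **MAD** — signed perpendicular distance of the projected knee centre from
  the projected FHC–AJC line, positive when the mechanical axis passes
  medial to the knee centre (varus deviation), per the usual convention.

Limbs are evaluated in their side-canonical (+x = lateral) representation,
so mirrored limbs yield identical values by construction. The knee centre
used for MAD is configurable: the femoral notch point (default), the tibial
knee centre, or their midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .geometry import angle_2d, project_coronal, signed_point_line_distance_2d
from .limb_model import LimbModel, reflect_to_lateral_x

KNEE_CENTRE_OPTIONS = ("fnp", "tkc", "midpoint")
PARAMETERS = ("hka", "mpta", "mldfa", "mad")


@dataclass
class MeasurementRecord:
    """Projected measurements of one leg in one pose, plus deltas to zero pose."""

    patient_id: str
    side: str
    rotation_deg: float
    flexion_deg: float
    hka: float
    mpta: float
    mldfa: float
    mad: float
    d_hka: float
    d_mpta: float
    d_mldfa: float
    d_mad: float


def _lateral_view(limb: LimbModel) -> LimbModel:
    if limb.canonical or limb.side == "right":
        return limb
    return reflect_to_lateral_x(limb)


def _proj(limb: LimbModel, name: str) -> np.ndarray:
    return project_coronal(limb.landmarks[name])


def _axis_vec(limb: LimbModel, a: str, b: str) -> np.ndarray:
    v = _proj(limb, b) - _proj(limb, a)
    if np.linalg.norm(v) < 1e-9:
        raise DegenerateGeometryError(f"landmarks {a} and {b} project onto the same point")
    return v


def measure_hka(limb: LimbModel) -> float:
    """Hip–knee–ankle angle (deg); 180 = collinear axes, < 180 varus."""
    limb = _lateral_view(limb)
    u = _axis_vec(limb, "FNP", "FHC")   # knee -> hip
    w = _axis_vec(limb, "TKC", "AJC")   # knee -> ankle
    theta_f = np.arctan2(-u[0], u[1])   # medial tilt of the femoral axis
    theta_t = np.arctan2(-w[0], -w[1])  # medial tilt of the tibial axis
    return 180.0 - float(np.degrees(theta_f + theta_t))


def measure_mpta(limb: LimbModel) -> float:
    """Medial proximal tibial angle (deg)."""
    limb = _lateral_view(limb)
    w = _axis_vec(limb, "TKC", "AJC")
    m = _axis_vec(limb, "LTP", "MTP")   # plateau line, pointing medially
    return angle_2d(w, m)


def measure_mldfa(limb: LimbModel) -> float:
    """Mechanical lateral distal femoral angle (deg)."""
    limb = _lateral_view(limb)
    u = _axis_vec(limb, "FNP", "FHC")
    l = _axis_vec(limb, "MDC", "LDC")   # condylar line, pointing laterally
    return angle_2d(u, l)


def knee_centre_2d(limb: LimbModel, knee_centre: str = "fnp") -> np.ndarray:
    """Projected knee-centre point used for the MAD measurement."""
    if knee_centre not in KNEE_CENTRE_OPTIONS:
        raise ValidationError(f"knee_centre must be one of {KNEE_CENTRE_OPTIONS}")
    limb = _lateral_view(limb)
    if knee_centre == "fnp":
        return _proj(limb, "FNP")
    if knee_centre == "tkc":
        return _proj(limb, "TKC")
    return 0.5 * (_proj(limb, "FNP") + _proj(limb, "TKC"))


def measure_mad(limb: LimbModel, knee_centre: str = "fnp") -> float:
    """Mechanical axis deviation (mm), medial passage of the axis positive."""
    k = knee_centre_2d(limb, knee_centre)
    limb = _lateral_view(limb)
    return signed_point_line_distance_2d(k, _proj(limb, "FHC"), _proj(limb, "AJC"),
                                         medial_sign=1.0)


def measure_all(limb: LimbModel, knee_centre: str = "fnp") -> dict[str, float]:
    """All four projected parameters as a dict keyed by parameter name."""
    return {
        "hka": measure_hka(limb),
        "mpta": measure_mpta(limb),
        "mldfa": measure_mldfa(limb),
        "mad": measure_mad(limb, knee_centre),
    }
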