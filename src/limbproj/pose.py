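"""Apply rotation/flexion combinations to a neutral limb.

The simulated manoeuvre mirrors how a malpositioned long-leg radiograph
comes about: the knee flexes about the transepicondylar axis — half of the
flexion on the femoral side, half on the tibial side in the reverse
direction — the tibia internally rotates with flexion (screw-home motion,
ramping to 5° over the first 20° of flexion), the whole limb is axially
rotated about the longitudinal mechanical axis, and finally the limb is
re-verticalized in the sagittal plane so the FHC→ankle line is upright, as
it would be in a standing acquisition.

Sign conventions: rotation positive = external rotation (for either leg,
since simulation always runs in the side-canonical +x-lateral frame);
flexion is positive and moves the knee anteriorly relative to the
hip–ankle line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import Axis3, rotate_about_axis
from .limb_model import FEMORAL_LANDMARKS, TIBIAL_LANDMARKS, LimbModel

ROTATION_GRID = (-15, -10, -5, 0, 5, 10, 15)
FLEXION_GRID = (0, 10, 20, 30)


@dataclass(frozen=True)
class Pose:
    """One (rotation, flexion) combination from the 7 x 4 study grid."""

    rotation_deg: float
    flexion_deg: float

    def __post_init__(self) -> None:
        if self.rotation_deg not in ROTATION_GRID:
            raise ValidationError(f"rotation_deg must be one of {ROTATION_GRID}")
        if self.flexion_deg not in FLEXION_GRID:
            raise ValidationError(f"flexion_deg must be one of {FLEXION_GRID}")


@dataclass
class SimOptions:
    """Kinematic options of the pose pipeline.

    ``screw_home_max_deg`` of tibial internal rotation is reached linearly at
    ``screw_home_ramp_end_deg`` of flexion and held constant beyond (set the
    maximum to 0 to disable). ``flexion_split`` is the femoral share of the
    flexion. ``rotation_axis`` selects the longitudinal axis used for the
    axial-rotation step: the post-flexion FHC→AJC line (default) or the
    neutral-pose line.
    """

    screw_home_max_deg: float = 5.0
    screw_home_ramp_end_deg: float = 20.0
    flexion_split: float = 0.5
    realign_vertical: bool = True
    rotation_axis: str = "post_flexion"

    def validate(self) -> None:
        if not 0.0 <= self.flexion_split <= 1.0:
            raise ValidationError("flexion_split must lie in [0, 1]")
        if self.screw_home_ramp_end_deg <= 0:
            raise ValidationError("screw_home_ramp_end_deg must be positive")
        if self.rotation_axis not in ("post_flexion", "neutral"):
            raise ValidationError("rotation_axis must be 'post_flexion' or 'neutral'")


def enumerate_poses(rotation_max: float = 15.0, flexion_max: float = 30.0) -> list[Pose]:
    """The rotation-major pose grid; the full grid has 7 x 4 = 28 cells."""
    return [
        Pose(r, f)
        for r in ROTATION_GRID
        if abs(r) <= rotation_max
        for f in FLEXION_GRID
        if f <= flexion_max
    ]


def screw_home_deg(flexion_deg: float, opts: SimOptions | None = None) -> float:
    """Tibial internal rotation (deg) coupled to knee flexion.

    Linear ramp from 0 at full extension to the maximum at the ramp end,
    constant for deeper flexion.
    """
    opts = opts or SimOptions()
    if flexion_deg < 0:
        raise ValidationError("flexion_deg must be >= 0")
    frac = min(flexion_deg / opts.screw_home_ramp_end_deg, 1.0)
    return opts.screw_home_max_deg * frac


def _rotate_group(limb: LimbModel, names: tuple[str, ...], axis: Axis3,
                  angle_deg: float, cloud: bool = False) -> None:
    if angle_deg == 0.0:
        return
    for name in names:
        limb.landmarks[name] = rotate_about_axis(limb.landmarks[name], axis, angle_deg)
    if cloud and limb.epicondylar_cloud is not None:
        limb.epicondylar_cloud = rotate_about_axis(limb.epicondylar_cloud, axis, angle_deg)


def apply_pose(limb: LimbModel, pose: Pose, opts: SimOptions | None = None) -> LimbModel:
    """Pose a neutral canonical limb; each bone segment stays rigid.

    Pipeline order: (1) split flexion about the transepicondylar axis,
    (2) screw-home internal rotation of the tibia about its (current)
    mechanical axis, (3) axial rotation of the whole limb about the
    longitudinal mechanical axis, (4) sagittal re-verticalization of the
    FHC→AJC line about the global x-axis.
    """
    opts = opts or SimOptions()
    opts.validate()
    if not limb.canonical:
        raise ValidationError("apply_pose requires a limb in the neutral canonical frame "
                              "(see frame.canonicalize)")
    out = limb.copy()
    lm = out.landmarks
    neutral_axis = Axis3.through_points(lm["FHC"], lm["AJC"])  # points caudally

    f = float(pose.flexion_deg)
    r = float(pose.rotation_deg)

    # (1) flexion split about the transepicondylar axis (+x, lateral).
    if f != 0.0:
        tea = Axis3(0.5 * (lm["MEC"] + lm["LEC"]),
                    (lm["LEC"] - lm["MEC"]) / np.linalg.norm(lm["LEC"] - lm["MEC"]))
        _rotate_group(out, FEMORAL_LANDMARKS, tea, +opts.flexion_split * f, cloud=True)
        _rotate_group(out, TIBIAL_LANDMARKS, tea, -(1.0 - opts.flexion_split) * f)

    # (2) screw-home: internal tibial rotation about the current tibial
    # mechanical axis (TKC and AJC lie on the axis and stay fixed).
    s = screw_home_deg(f, opts)
    if s != 0.0:
        tib_axis = Axis3.through_points(lm["TKC"], lm["AJC"])  # caudal direction
        _rotate_group(out, TIBIAL_LANDMARKS, tib_axis, -s)     # + about caudal = external

    # (3) axial rotation of the whole limb, positive = external.
    if r != 0.0:
        if opts.rotation_axis == "post_flexion":
            long_axis = Axis3.through_points(lm["FHC"], lm["AJC"])
        else:
            long_axis = neutral_axis
        _rotate_group(out, FEMORAL_LANDMARKS + TIBIAL_LANDMARKS, long_axis, r, cloud=True)

    # (4) re-verticalize the FHC -> ankle line in the sagittal plane.
    if opts.realign_vertical:
        d = lm["FHC"] - lm["AJC"]
        alpha = np.degrees(np.arctan2(d[1], d[2]))
        if alpha != 0.0:
            x_axis = Axis3(lm["AJC"].copy(), np.array([1.0, 0.0, 0.0]))
            _rotate_group(out, FEMORAL_LANDMARKS + TIBIAL_LANDMARKS, x_axis, alpha, cloud=True)

    return out
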