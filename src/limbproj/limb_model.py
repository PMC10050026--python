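"""Synthetic lower-limb landmark models.

The study population this package emulates is a cohort of 60 legs (30
patients, both sides) whose neutral-position projected alignment follows the
reported summary statistics: HKA 180.1 ± 3.1°, MPTA 87.7 ± 2.6°,
mLDFA 87.2 ± 2.2°, with the mechanical axis deviation (~6.2 mm medial)
emerging from the construction rather than being targeted directly.

No landmark coordinates are available for the original CT-derived bones, so
limbs are built procedurally by inverse construction: the femoral notch
point (FNP) sits at the origin, the femoral head centre (FHC) and ankle
joint centre (AJC) are placed so the projected mechanical axes realize the
target HKA exactly, and the distal femoral / proximal tibial joint lines are
tilted to realize the target mLDFA and MPTA exactly. Anteroposterior
structure (condyle and plateau offsets, the epicondylar cylinder cloud) does
not affect neutral coronal projections but drives how measurements distort
under axial rotation and flexion.

Canonical frame: +x lateral, +y anterior, +z cranial. Limbs are constructed
in this right-handed frame; left legs are stored mirrored (x negated,
medial/lateral labels swapped).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConstructionError, ValidationError

REQUIRED_LANDMARKS = ("FHC", "FNP", "TKC", "AJC", "MDC", "LDC", "MTP", "LTP", "MEC", "LEC")
FEMORAL_LANDMARKS = ("FHC", "FNP", "MDC", "LDC", "MEC", "LEC")
TIBIAL_LANDMARKS = ("TKC", "AJC", "MTP", "LTP")
_MIRROR_PAIRS = (("MDC", "LDC"), ("MTP", "LTP"), ("MEC", "LEC"))

SCHEMA_VERSION = 1


@dataclass
class AnatomyParams:
    """Anatomy and alignment targets for one constructed leg.

    Lengths in mm, angles in degrees. The three ``target_*`` angles are the
    neutral-pose projected values the construction realizes exactly; AP
    offsets control rotation sensitivity of the projected joint lines.
    """

    femur_length: float = 410.0
    tibia_length: float = 370.0
    knee_width: float = 80.0
    condyle_ap_offset: float = 25.0      # posterior offset of distal condyle points vs TEA
    condyle_ap_asymmetry: float = 3.0    # medial condyle point this much more posterior
    plateau_ap_asymmetry: float = 2.0    # medial plateau point this much more posterior
    tibial_offset_x: float = -12.5       # mediolateral shift of tibial axis vs FNP (- = medial)
    tkc_drop: float = 4.0                # TKC below FNP
    condyle_drop: float = 15.0           # distal condylar line below FNP
    tea_offset_z: float = 8.0            # transepicondylar axis above FNP
    epicondyle_halfwidth: float = 45.0
    epicondyle_radius: float = 22.0
    deformity_femoral_share: float = 0.5
    target_hka: float = 180.1
    target_mpta: float = 87.7
    target_mldfa: float = 87.2
    side: str = "right"

    def validate(self) -> None:
        for name in ("femur_length", "tibia_length", "knee_width",
                     "epicondyle_halfwidth", "epicondyle_radius"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 160.0 <= self.target_hka <= 200.0:
            raise ValidationError("target_hka outside [160, 200] deg")
        for name in ("target_mpta", "target_mldfa"):
            if not 75.0 <= getattr(self, name) <= 100.0:
                raise ValidationError(f"{name} outside [75, 100] deg")
        if not 0.0 <= self.deformity_femoral_share <= 1.0:
            raise ValidationError("deformity_femoral_share must lie in [0, 1]")
        if self.side not in ("left", "right"):
            raise ValidationError("side must be 'left' or 'right'")


@dataclass
class LimbModel:
    """One leg: named 3-D landmarks plus identity and construction params."""

    patient_id: str
    side: str
    landmarks: dict[str, np.ndarray]
    epicondylar_cloud: np.ndarray | None = None
    params: AnatomyParams | None = None
    canonical: bool = False
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.landmarks = {k: np.asarray(v, dtype=float) for k, v in self.landmarks.items()}
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.landmarks]
        if missing:
            raise ValidationError(f"missing required landmarks: {', '.join(missing)}")
        if self.epicondylar_cloud is not None:
            self.epicondylar_cloud = np.atleast_2d(np.asarray(self.epicondylar_cloud, dtype=float))

    def copy(self) -> "LimbModel":
        return LimbModel(
            patient_id=self.patient_id,
            side=self.side,
            landmarks={k: v.copy() for k, v in self.landmarks.items()},
            epicondylar_cloud=None if self.epicondylar_cloud is None else self.epicondylar_cloud.copy(),
            params=None if self.params is None else replace(self.params),
            canonical=self.canonical,
            extras=copy.deepcopy(self.extras),
        )


def construct_limb(params: AnatomyParams, patient_id: str = "P00") -> LimbModel:
    """Build a limb whose neutral projection hits the target angles exactly.

    The construction is closed-form: mechanical-axis tilts are split between
    femur and tibia by ``deformity_femoral_share`` of the total varus angle
    (180° − HKA), and the joint-line tilts are solved from the MPTA/mLDFA
    targets given those axis tilts. The epicondylar cloud lies exactly on a
    cylinder about the MEC–LEC chord (the transepicondylar axis), which is
    parallel to +x in the canonical frame.
    """
    params.validate()
    p = params
    varus = np.deg2rad(180.0 - p.target_hka)
    theta_f = varus * p.deformity_femoral_share
    theta_t = varus * (1.0 - p.deformity_femoral_share)
    phi_f = theta_f + np.deg2rad(90.0 - p.target_mldfa)   # condylar lateral-end elevation
    psi_t = np.deg2rad(90.0 - p.target_mpta) - theta_t    # plateau lateral-end elevation

    lm: dict[str, np.ndarray] = {}
    lm["FNP"] = np.zeros(3)
    lm["FHC"] = p.femur_length * np.array([-np.sin(theta_f), 0.0, np.cos(theta_f)])
    tkc = np.array([p.tibial_offset_x, 0.0, -p.tkc_drop])
    lm["TKC"] = tkc
    lm["AJC"] = tkc + p.tibia_length * np.array([-np.sin(theta_t), 0.0, -np.cos(theta_t)])

    half = 0.5 * p.knee_width
    cond_centre = np.array([0.0, 0.0, -p.condyle_drop])
    cond_dir = np.array([np.cos(phi_f), 0.0, np.sin(phi_f)])
    lm["MDC"] = cond_centre - half * cond_dir + np.array(
        [0.0, -(p.condyle_ap_offset + 0.5 * p.condyle_ap_asymmetry), 0.0])
    lm["LDC"] = cond_centre + half * cond_dir + np.array(
        [0.0, -(p.condyle_ap_offset - 0.5 * p.condyle_ap_asymmetry), 0.0])

    plat_dir = np.array([np.cos(psi_t), 0.0, np.sin(psi_t)])
    lm["MTP"] = tkc - half * plat_dir + np.array([0.0, -0.5 * p.plateau_ap_asymmetry, 0.0])
    lm["LTP"] = tkc + half * plat_dir + np.array([0.0, +0.5 * p.plateau_ap_asymmetry, 0.0])

    tea_centre = np.array([0.0, 0.0, p.tea_offset_z])
    lm["MEC"] = tea_centre - np.array([p.epicondyle_halfwidth, 0.0, 0.0])
    lm["LEC"] = tea_centre + np.array([p.epicondyle_halfwidth, 0.0, 0.0])

    xs = np.linspace(-0.8, 0.8, 8) * p.epicondyle_halfwidth
    angs = np.linspace(np.deg2rad(-110), np.deg2rad(110), 9)
    cloud = np.array([
        tea_centre + np.array([x, p.epicondyle_radius * np.sin(a), -p.epicondyle_radius * np.cos(a)])
        for x in xs for a in angs
    ])

    if not (lm["FHC"][2] > lm["FNP"][2] > lm["AJC"][2]):
        raise ConstructionError("degenerate construction: hip/knee/ankle not ordered cranio-caudally")

    limb = LimbModel(patient_id=patient_id, side="right", landmarks=lm,
                     epicondylar_cloud=cloud, params=replace(p, side="right"),
                     canonical=True)
    if params.side == "left":
        limb = mirror_limb(limb)
    return limb


def mirror_limb(limb: LimbModel) -> LimbModel:
    """Mirror a limb across the sagittal midplane (negate x, swap M/L labels).

    An involution: mirroring twice restores the original coordinates. All
    four projected measurements are invariant under mirroring because the
    measurement layer evaluates every limb in its side-canonical frame.
    """
    out = limb.copy()
    for name, v in out.landmarks.items():
        v[0] = -v[0]
    for a, b in _MIRROR_PAIRS:
        out.landmarks[a], out.landmarks[b] = out.landmarks[b], out.landmarks[a]
    if out.epicondylar_cloud is not None:
        out.epicondylar_cloud[:, 0] *= -1.0
    out.side = "left" if limb.side == "right" else "right"
    if out.params is not None:
        out.params = replace(out.params, side=out.side)
    # Mirroring leaves the side-canonical (+x = lateral) frame, so the result
    # must be re-canonicalized before posing.
    out.canonical = False
    return out


def reflect_to_lateral_x(limb: LimbModel) -> LimbModel:
    """Internal reflection of a left limb into the +x = lateral frame.

    Unlike :func:`mirror_limb` this keeps the side label: it changes the
    representation, not the identity. Right limbs — and limbs already flagged
    canonical — pass through unchanged.
    """
    if limb.side == "right" or limb.canonical:
        return limb.copy()
    out = limb.copy()
    for v in out.landmarks.values():
        v[0] = -v[0]
    for a, b in _MIRROR_PAIRS:
        out.landmarks[a], out.landmarks[b] = out.landmarks[b], out.landmarks[a]
    if out.epicondylar_cloud is not None:
        out.epicondylar_cloud[:, 0] *= -1.0
    return out


@dataclass
class PopulationSpec:
    """Sampling specification for the synthetic cohort.

    Angle targets are drawn as patient-shared plus leg-specific Gaussian
    deviations (``shared_fraction`` of the variance is common to both legs of
    a patient, making a patient-level random intercept identifiable),
    truncated at ``truncation_sd`` standard deviations to exclude severe
    deformity. With ``calibrate_moments`` the drawn targets are affinely
    standardized so the cohort sample mean and SD equal the specified values
    exactly — the cohort is defined by its summary statistics, not just drawn
    from them.
    """

    n_patients: int = 30
    seed: int = 0
    hka_mean: float = 180.1
    hka_sd: float = 3.1
    mpta_mean: float = 87.7
    mpta_sd: float = 2.6
    mldfa_mean: float = 87.2
    mldfa_sd: float = 2.2
    shared_fraction: float = 0.85
    truncation_sd: float = 3.0
    calibrate_moments: bool = True
    femur_mean: float = 410.0
    femur_sd: float = 25.0
    tibia_mean: float = 370.0
    tibia_sd: float = 20.0
    knee_width_mean: float = 80.0
    knee_width_sd: float = 5.0
    condyle_ap_offset_mean: float = 25.0
    condyle_ap_offset_sd: float = 3.0
    tibial_offset_mean: float = -12.5
    tibial_offset_sd: float = 4.0
    condyle_ap_asymmetry: float = 3.0
    plateau_ap_asymmetry: float = 2.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        for name in ("hka_sd", "mpta_sd", "mldfa_sd", "femur_sd", "tibia_sd",
                     "knee_width_sd", "condyle_ap_offset_sd", "tibial_offset_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValidationError("shared_fraction must lie in [0, 1]")
        if self.truncation_sd <= 0:
            raise ValidationError("truncation_sd must be positive")


def _truncated_normal(rng: np.random.Generator, sd: float, size: int, bound_sd: float) -> np.ndarray:
    """Centred normal draws with |x| <= bound_sd * sd (redraw rejection)."""
    if sd == 0.0:
        return np.zeros(size)
    out = rng.normal(0.0, sd, size)
    bad = np.abs(out) > bound_sd * sd
    while np.any(bad):
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
        bad = np.abs(out) > bound_sd * sd
    return out


def _paired_angle_draws(rng: np.random.Generator, mean: float, sd: float,
                        spec: PopulationSpec) -> np.ndarray:
    """Per-leg angle targets (length 2n, legs of a patient adjacent)."""
    n = spec.n_patients
    sd_b = sd * np.sqrt(spec.shared_fraction)
    sd_e = sd * np.sqrt(1.0 - spec.shared_fraction)
    b = _truncated_normal(rng, sd_b, n, spec.truncation_sd) if sd_b > 0 else np.zeros(n)
    e = _truncated_normal(rng, sd_e, 2 * n, spec.truncation_sd) if sd_e > 0 else np.zeros(2 * n)
    vals = mean + np.repeat(b, 2) + e
    if spec.calibrate_moments and sd > 0 and len(vals) > 1:
        dev = vals - vals.mean()
        s = dev.std(ddof=1)
        if s > 1e-12:
            vals = mean + dev * (sd / s)
        else:
            vals = np.full_like(vals, mean)
    return vals


def generate_population(spec: PopulationSpec) -> list[LimbModel]:
    """Generate ``2 * n_patients`` limbs (right then left per patient)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    hka = _paired_angle_draws(rng, spec.hka_mean, spec.hka_sd, spec)
    mpta = _paired_angle_draws(rng, spec.mpta_mean, spec.mpta_sd, spec)
    mldfa = _paired_angle_draws(rng, spec.mldfa_mean, spec.mldfa_sd, spec)

    femur = spec.femur_mean + _truncated_normal(rng, spec.femur_sd, n, spec.truncation_sd)
    tibia = spec.tibia_mean + _truncated_normal(rng, spec.tibia_sd, n, spec.truncation_sd)
    kw = spec.knee_width_mean + _truncated_normal(rng, spec.knee_width_sd, n, spec.truncation_sd)
    cap = spec.condyle_ap_offset_mean + _truncated_normal(
        rng, spec.condyle_ap_offset_sd, n, spec.truncation_sd)
    toff = spec.tibial_offset_mean + _truncated_normal(
        rng, spec.tibial_offset_sd, 2 * n, spec.truncation_sd)

    limbs: list[LimbModel] = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        for j, side in enumerate(("right", "left")):
            k = 2 * i + j
            params = AnatomyParams(
                femur_length=float(femur[i]),
                tibia_length=float(tibia[i]),
                knee_width=float(kw[i]),
                condyle_ap_offset=float(cap[i]),
                condyle_ap_asymmetry=spec.condyle_ap_asymmetry,
                plateau_ap_asymmetry=spec.plateau_ap_asymmetry,
                tibial_offset_x=float(toff[k]),
                target_hka=float(hka[k]),
                target_mpta=float(mpta[k]),
                target_mldfa=float(mldfa[k]),
                side=side,
            )
            limbs.append(construct_limb(params, patient_id=pid))
    return limbs


# --------------------------------------------------------------------------
# Landmark file I/O
#
# Schema (JSON, units mm, axes: x mediolateral / y anteroposterior /
# z longitudinal; left legs stored in anatomical coordinates):
# {
#   "schema_version": 1,
#   "limbs": [
#     {"patient_id": "P01", "side": "right",
#      "landmarks": {"FHC": [x, y, z], ...},        # all ten required names
#      "epicondylar_cloud": [[x, y, z], ...],       # optional
#      ... any unknown fields are preserved on round-trip ...}
#   ]
# }
# --------------------------------------------------------------------------

_KNOWN_LIMB_KEYS = {"patient_id", "side", "landmarks", "epicondylar_cloud", "canonical"}


def write_landmarks(models: list[LimbModel], path: str | Path) -> None:
    """Serialize limbs to the documented JSON landmark schema."""
    limbs = []
    for m in models:
        entry: dict = {
            "patient_id": m.patient_id,
            "side": m.side,
            "canonical": bool(m.canonical),
            "landmarks": {k: [float(x) for x in v] for k, v in m.landmarks.items()},
        }
        if m.epicondylar_cloud is not None:
            entry["epicondylar_cloud"] = [[float(x) for x in p] for p in m.epicondylar_cloud]
        entry.update(m.extras)
        limbs.append(entry)
    payload = {"schema_version": SCHEMA_VERSION, "units": "mm",
               "axes": "x mediolateral, y anteroposterior, z longitudinal", "limbs": limbs}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path: str | Path) -> list[LimbModel]:
    """Parse the JSON landmark schema back into ``LimbModel`` objects."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict) or "limbs" not in payload:
        raise ValidationError("landmark file must be an object with a 'limbs' list")
    models = []
    for i, entry in enumerate(payload["limbs"]):
        where = f"limbs[{i}]"
        for key in ("patient_id", "side", "landmarks"):
            if key not in entry:
                raise ValidationError(f"{where}: missing field '{key}'")
        if entry["side"] not in ("left", "right"):
            raise ValidationError(f"{where}: side must be 'left' or 'right'")
        lm = {}
        for name in REQUIRED_LANDMARKS:
            if name not in entry["landmarks"]:
                raise ValidationError(f"{where}: missing landmark '{name}'")
            v = np.asarray(entry["landmarks"][name], dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValidationError(f"{where}: landmark '{name}' must be a finite [x, y, z]")
            lm[name] = v
        for name, v in entry["landmarks"].items():
            if name not in lm:
                lm[name] = np.asarray(v, dtype=float)
        cloud = entry.get("epicondylar_cloud")
        extras = {k: v for k, v in entry.items() if k not in _KNOWN_LIMB_KEYS}
        models.append(LimbModel(
            patient_id=str(entry["patient_id"]),
            side=entry["side"],
            landmarks=lm,
            epicondylar_cloud=None if cloud is None else np.asarray(cloud, dtype=float),
            canonical=bool(entry.get("canonical", False)),
            extras=extras,
        ))
    return models
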