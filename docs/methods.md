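# Methods

## Overview

`limbproj` answers a projection-geometry question: how far do the standard
frontal-radiograph alignment measurements (HKA, MPTA, mLDFA, MAD) move when
the imaged limb is axially rotated and/or flexed instead of standing in the
standardized neutral position? The pipeline has four stages — synthetic
anatomy, frame normalization, pose simulation, projected measurement — plus
a mixed-model analysis layer. Everything is deterministic given the
population seed.

## Synthetic anatomy

No landmark coordinates exist for the CT-derived cohort the study design
refers to, so the generator builds limbs by *inverse construction*: it
places landmarks so the neutral coronal projection realizes prescribed
target angles exactly (closed form, no iteration).

Canonical frame: +x lateral, +y anterior, +z cranial, origin at the femoral
notch point (FNP). For a total coronal deformity `v = 180° − HKA`, a share
(default one half) is assigned to the femoral mechanical axis and the rest
to the tibial axis; joint-line tilts are then solved from the MPTA/mLDFA
targets given those axis tilts. Anteroposterior structure — condyle and
plateau AP offsets, the epicondylar cylinder cloud — does not alter neutral
projections (the projection discards y) but fully determines how
measurements distort under rotation and flexion.

Key defaults (all configurable per limb via `AnatomyParams`, population-wise
via `PopulationSpec`):

| parameter | default | why |
|---|---|---|
| femur / tibia length | 410 / 370 mm (SD 25 / 20) | adult lower-limb anthropometry; sets the lever arms of the flexion-induced knee displacement |
| knee width | 80 mm (SD 5) | condylar/plateau span for joint-line projections |
| condyle AP offset | 25 mm | distal condyle points sit posterior to the flexion axis |
| condyle / plateau AP asymmetry | 3 / 2 mm | medial side more posterior; calibrated analytically so the per-degree rotation responses of mLDFA and MPTA have the small reported magnitudes rather than zero |
| tibial mediolateral offset | −12.5 mm (SD 4) | shifts the tibial mechanical axis medially relative to FNP; calibrated so the emergent neutral MAD mean is ≈ 6.2 mm (see below) |
| angle targets | HKA 180.1 ± 3.1°, MPTA 87.7 ± 2.6°, mLDFA 87.2 ± 2.2° | reference cohort summary statistics |
| shared variance fraction | 0.85 | fraction of angle-target variance common to both legs of a patient; chosen so the patient random intercept reproduces a conditional R² ≈ 0.93 for the HKA model (see *Statistics*) |
| truncation | ±3 SD | excludes severe deformity, mirroring cohort inclusion criteria |

**Cohort moment calibration.** Drawn angle targets are affinely standardized
so the 60-leg sample mean and SD equal the specified values exactly. The
cohort is thereby *defined by* its summary statistics rather than merely
drawn from them; with `calibrate_moments=False` plain truncated-normal
sampling is used.

**MAD is emergent, not targeted.** Given the landmark definitions, the
projected MAD to a knee centre that averages FNP and TKC is algebraically
locked to ≈ `(Lf·Lt/(Lf+Lt))·sin(180° − HKA)`: any common mediolateral
offset cancels between the knee centre and the hip–ankle line, so a cohort
with mean HKA 180.1° would be forced to mean MAD ≈ −0.3 mm. A cohort can
only exhibit the reported pair (HKA 180.1°, MAD +6.2 mm) if the knee centre
used for MAD is a single-bone landmark that is mediolaterally offset from
the hip–ankle line. The package therefore measures MAD to the **FNP** by
default (TKC and midpoint remain available via `knee_centre=`), and the
generator's tibial mediolateral offset realizes the +6.2 mm mean. The MAD
population SD that emerges (≈ 10 mm) is somewhat above the reported ±8.4 mm
because HKA spread alone already implies ≈ 10 mm; matching it would require
a negative correlation between offset and deformity that the source
statistics do not constrain.

## Frame

Each limb is normalized before posing (`frame.canonicalize`): left limbs are
reflected into the +x-lateral representation (side label kept — measurement
conventions are thereby side-invariant), the transepicondylar axis is
estimated as the axis of a least-squares cylinder through the epicondylar
point cloud (Gauss–Newton via `scipy.optimize.least_squares`, initialized
from the epicondyle-centre chord; the chord is the fallback when no cloud is
present), the longitudinal axis is the Gram–Schmidt complement of
(FHC − FNP) against that axis, and the limb is rigidly mapped onto the
canonical axes with the FNP at the origin.

## Pose pipeline

`apply_pose` executes, in order:

1. **Flexion split** — femoral landmarks rotate by `+split·f`, tibial
   landmarks by `−(1−split)·f`, both about the transepicondylar axis
   (default split 0.5). The knee consequently translates anteriorly relative
   to the hip–ankle line; its AP offset is the lever that turns axial
   rotation into projected varus/valgus.
2. **Screw-home** — the tibia internally rotates about its current
   mechanical axis (TKC→AJC), ramping linearly from 0° at extension to 5° at
   20° flexion and constant beyond. The ramp (rather than a step) is a
   documented reading of "5° over the terminal 20°"; both are available via
   `SimOptions`.
3. **Axial rotation** — the whole limb rotates about the longitudinal
   mechanical axis, positive = external. Default axis: the post-flexion
   FHC→AJC line; the neutral-pose axis is available
   (`rotation_axis="neutral"`) and is the configuration under which the
   closed-form identity `ΔHKA = atan(tan f · sin r)` holds exactly.
4. **Re-verticalization** — the limb rotates about the global x-axis until
   the FHC→AJC line has no sagittal inclination, emulating upright standing
   at acquisition. Coronal obliquity is deliberately preserved.

The operation order is fixed and pinned by tests; each bone segment is rigid
to ≤ 1e−9 mm throughout. Zero-pose rows are computed through the same code
path, so deltas at (0, 0) are exactly zero.

## Measurement

Measurements are taken on the orthographic coronal projection *(x, z)*.
HKA is computed from the signed medial tilts of the two projected mechanical
axes (`180° − (θ_f + θ_t)`), which keeps varus/valgus continuous through
180°. MPTA and mLDFA are the angles between a projected mechanical axis and
the corresponding projected joint line, taken on the medial/lateral side by
orienting the joint-line vector medially/laterally. MAD is the signed
point-line distance of the projected knee centre from the projected FHC–AJC
line, positive when the axis passes medially (varus convention). Deltas are
`value(pose) − value(zero pose)` per limb, so `d_hka < 0` is a varus shift.

## Statistics

Per outcome (`hka`, `mpta`, `mldfa`, `mad`):
`outcome ~ C(rotation)*C(flexion) + C(side)` with a patient random
intercept, fitted by **ML** (statsmodels `MixedLM`; several optimizers are
attempted and the best finite-likelihood fit kept, because near-boundary
variance components can make a single optimizer diverge). Likelihood-ratio
tests: rotation = main-effects model vs flexion-only (df 6), flexion =
main-effects vs rotation-only (df 3), interaction = full vs main-effects
(df 18). The BH family is all 12 p-values across the four models by default
(`bh_family="per_model"` available); α = 0.05. Conditional R² is
Nakagawa–Schielzeth with the fixed-effect variance computed as the variance
of the fixed linear predictor. Marginal cell predictions average the side
factor with equal weights and carry delta-method Wald 95% CIs; on the
balanced grid they coincide with raw cell means. `per_degree_slopes`
linearizes each delta against rotation degree within each flexion level by
least squares.

## What the generator does and does not emulate

It emulates: paired-leg cohort structure with patient-level correlation,
the reference neutral-alignment statistics (exactly, by moment
calibration), segment-length and knee-geometry variability, and the AP
structure that makes projections pose-sensitive. It does **not** emulate:
real cortical/articular surface geometry (landmarks only), weight-bearing
deformation, soft-tissue kinematics or femoral rollback, and — notably —
sagittal inclination of the mechanical axes in the neutral pose. Because the
constructed axes lie exactly in the coronal plane at neutral, rotation
*alone* leaves the projected measurements almost unchanged (slopes ≲
0.01 °/°), whereas real cohorts show small nonzero extended-knee rotation
responses (~0.02–0.04 °/°) attributable to physiological sagittal offsets.
Introducing such offsets would, with the default segment lengths, push the
deep-flexion MAD endpoint beyond its reference value, so neutral axes were
kept coronal; passing tests on the combined-effect magnitudes therefore
carry no evidence about rotation-only responses of real anatomy.

## Numerical choices and degenerate inputs

Rotations use `scipy.spatial.transform.Rotation` (Rodrigues); zero-angle
steps are skipped so identity poses are bitwise identity. Axis directions
must be unit to 1e−9. `angle_2d` clips the cosine into [−1, 1]; zero
vectors, coincident line points and coincident landmarks raise
`DegenerateGeometryError`. The cylinder fit requires ≥ 8 non-collinear
points (collinearity via singular-value ratio < 1e−8) and raises
`ConvergenceError` on optimizer failure. Mixed-model fits warn (not fail)
when the patient variance collapses to the boundary. The landmark JSON
schema is versioned; unknown per-limb fields survive a round-trip.

## Problem sizes

The default study (60 limbs × 28 poses, four mixed models with four nested
fits each) runs in a few seconds on one core. Test-suite simulations use the
same default cohort once (session fixture) and smaller cohorts (2–12
patients) for CLI, recovery and null-calibration checks; the
false-positive-rate check uses 50 replicates of a 6-patient grid.

## Known limitations

* MAD SD exceeds the reference ±8.4 mm for the reasons above.
* The reported deep-flexion endpoints (|ΔHKA| ≈ 7.9°, |ΔMAD| ≈ 26 mm at
  ±15°/30°) sit within ~6% of the reference values (8.4–8.5°, 25.2–25.4 mm);
  the residual gap is anthropometry-dependent (shorter segments shrink the
  knee's anterior lever arm).
* Rotation and flexion grids are the study's discrete grids; arbitrary poses
  are out of scope by design.
* The screw-home axis and the rotation-axis choice (post-flexion vs
  neutral) are assumptions exposed as options, not validated kinematics.
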