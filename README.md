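# limbproj

**limbproj** simulates how axial rotation and knee flexion of the lower limb
distort the alignment measurements read off a frontal long-leg radiograph
(LLR). Pre- and postoperative alignment decisions — osteotomies, knee
arthroplasty — hinge on four projected parameters:

* **HKA** — hip–knee–ankle angle: the medial angle between the femoral
  mechanical axis (femoral head centre FHC → femoral notch point FNP) and the
  tibial mechanical axis (tibial knee centre TKC → ankle joint centre AJC);
  180° is neutral, < 180° varus.
* **MAD** — mechanical axis deviation: perpendicular distance of the knee
  centre from the FHC–AJC line (mm, medial passage of the axis positive).
* **MPTA / mLDFA** — medial proximal tibial angle and mechanical lateral
  distal femoral angle: the joint-line angles of tibia and femur against
  their mechanical axes.

An LLR is an orthographic projection: with anatomical axes *x* mediolateral,
*y* anteroposterior and *z* longitudinal, the image shows only *(x, z)*. A
limb that is axially rotated by *r* and flexed by *f* at the moment of
exposure projects differently, e.g. for flexion carried by one segment the
projected HKA shifts by the closed-form amount

```
ΔHKA = atan( tan f · sin r )
```

— small for either motion alone, large for the combination (30° flexion with
15° rotation projects as an 8.5° pseudo-deformity).

The package models a cohort of 60 legs (30 patients, both sides) as 3-D
landmark sets whose neutral projections follow the reported reference
statistics (HKA 180.1 ± 3.1°, MPTA 87.7 ± 2.6°, mLDFA 87.2 ± 2.2°, MAD
≈ 6.2 mm), poses each leg on a 7 × 4 grid of rotations (±15° in 5° steps)
and flexions (0–30° in 10° steps) — with half-femoral/half-tibial flexion
split, screw-home tibial rotation and sagittal re-verticalization of the
hip–ankle line — and analyses the 1680 projected measurements with
per-parameter linear mixed-effects models (categorical rotation, flexion and
their interaction, a side effect, a patient-level random intercept,
likelihood-ratio tests with Benjamini–Hochberg adjustment, Nakagawa
conditional R²).

## Worked example

```python
from limbproj import PopulationSpec, generate_population
from limbproj.experiment import run_experiment, descriptive_deltas
from limbproj.stats import analyze_table

spec = PopulationSpec(seed=1)            # 30 patients x 2 legs
table = run_experiment(generate_population(spec), spec=spec)
cells = descriptive_deltas(table)
print(len(table.data))                    # 1680
print(round(cells.loc[(-15, 30), "d_hka_mean"], 2))   # 7.93
print(round(cells.loc[(15, 30), "d_mad_mean"], 2))    # 26.32
res = analyze_table(table)["hka"]
print(round(res.r2_conditional, 3))       # 0.969
print(res.lrt["interaction"].p_adjusted)  # 0.0
```

1680 is the full simulation count. The second and third numbers are the mean
distortions at the worst pose (30° flexion, 15° rotation): the projected HKA
reads ~7.9° more valgus/varus than it is, and the MAD shifts by ~26 mm —
an order of magnitude beyond clinical decision thresholds, although neither
rotation nor flexion alone moves the measurements much. The mixed model
attributes ~97% of measurement variance to pose effects plus stable patient
anatomy, and the rotation × flexion interaction dominates every parameter
(adjusted p ≈ 0).

The same study runs from the shell:

```bash
limbproj full --seed 1 --out runs/demo        # landmarks, CSVs, models, figures
limbproj simulate --n-patients 2 --no-plots --out runs/tiny
```

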