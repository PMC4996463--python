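# gliomark

Geometric and textural imaging biomarkers of bevacizumab (BVZ) response in
glioblastoma, computed from pretreatment postcontrast T1-weighted MRI
segmentations, together with the survival analysis that turns those markers
into patient subgroups.

Glioblastomas typically present as a contrast-enhancing (CE) rim around a
necrotic core. The package quantifies the geometry of that rim and asks
whether it predicts who benefits from antiangiogenic therapy:

- **Volumetry** — CE volume `V_CE`, inner/necrotic volume `V_I`, total volume
  `V = V_CE + V_I`, and the 3D maximal diameter `d_max`, all from a 3-label
  segmentation mask (background / CE rim / inner core) with voxel spacing in mm.
- **Spherical rim width** — the thickness of the sphere-equivalent shell with
  the same total and inner volumes:
  `δ_s = (3/(4π))^(1/3) · (V^(1/3) − V_I^(1/3)) ≈ 0.62 (V^(1/3) − V_I^(1/3))`.
- **Geometric heterogeneity** — from the pooled minimal distances between the
  inner and outer surfaces of the CE rim, `G_H = (δ4 − δ3)/δ4`, where δ3 and
  δ4 are the third quartile and the maximum of the rim-width distribution.
  `G_H ∈ [0, 1]`: 0 for a perfectly even rim, →1 for a highly uneven one.
- **Texture** — 16 heterogeneity measures from 3D gray-level co-occurrence
  and run-length matrices (entropy, homogeneity, contrast, dissimilarity,
  uniformity; LRE, SRE, LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLNU, RLNU,
  RPC) at 32 gray levels.
- **Survival layer** — Kaplan–Meier curves and medians, two-group log-rank
  tests, univariate Cox hazard ratios with Wald 95% CIs, Spearman marker
  correlations, and a threshold scan that searches every admissible marker
  cutpoint and selects the minimum of a smoothed log-rank p-profile.

A bundled 40-patient cohort table (overall survival, `V_I`, `G_H`, MGMT
status, treatment arm: 17 BVZ+ / 23 BVZ−) lets the survival layer reproduce
the published analysis; synthetic shell phantoms and simulated cohorts with
closed-form ground truth make every stage testable without patient data.

Intended users: researchers in quantitative neuro-oncology / radiomics who
have segmented NIfTI volumes and survival tables and want a tested, scripted
version of this biomarker analysis.

## Worked example

```python
from gliomark import ShellSpec, make_shell_phantom, geometric_features

# an even spherical shell: inner radius 10 mm, outer 20 mm, 1 mm voxels
vol = make_shell_phantom(ShellSpec(inner_radius=10.0, outer_radius_base=20.0))
f = geometric_features(vol)
print(f"V     = {f.v_cm3:.2f} cm^3")
print(f"delta_s = {f.delta_s_cm*10:.2f} mm")
print(f"G_H   = {f.g_h:.3f}")
```

prints

```
V     = 33.37 cm^3
delta_s = 10.01 mm
G_H   = 0.022
```

The voxelized shell volume is within 0.5% of the analytic 33.51 cm³; the
spherical rim width recovers the true 10 mm thickness; and `G_H` is close to
0 because the rim is even. A rim whose width is 10 mm on 20% of the solid
angle and 5 mm elsewhere instead gives `G_H = 0.500` — the closed-form
`1 − w1/w2` for a two-mass width distribution.

On the bundled cohort:

```bash
gliomark reproduce
```

prints, for each published quantity, the recomputed value and a pass flag —
e.g. median overall survival 10.78 months (range 2.30–52.33) over all 40
patients, mean/median `G_H` of 0.608/0.623 in the BVZ arm, Spearman
rho(V_I, G_H) = 0.519, and a BVZ-arm `G_H` split at 0.605 with hazard ratio
3.931 (95% CI 1.289–11.985, log-rank p = 0.011) under the all-events
assumption (the published table carries no censoring indicators).

Other CLI entry points: `gliomark simulate` (phantoms and synthetic
cohorts), `gliomark extract` (batch NIfTI feature extraction to CSV),
`gliomark analyze` (full survival report for a cohort CSV).

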