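# Methods

This note records the models, conventions and design choices behind
`gliomark`, in the order data flows through the package.

## Labeled volumes

A tumor is a 3D intensity grid plus a 3-label mask — background (0),
contrast-enhancing rim (1), inner/necrotic core (2) — and per-axis voxel
spacing in mm (slice thickness is simply the third spacing component; all
computations are anisotropy-safe). Tumors without CE voxels are rejected:
the rim measures are defined only for enhancing tumors. I/O is NIfTI-1 via
nibabel, with spacing taken from the header zooms.

## Rim geometry

**Volumes.** `V_CE`, `V_I` are label voxel counts times the voxel volume,
reported in cm³; `V = V_CE + V_I` holds exactly by construction.

**Spherical rim width.** `δ_s = (3/(4π))^(1/3) (V^(1/3) − V_I^(1/3))`, in cm.
For an ideal spherical shell this is exactly the shell thickness `R − r`;
the prefactor is 0.6204 (0.62 at two decimals).

**Maximal 3D diameter.** The largest Euclidean distance between tumor voxel
centers, in cm. Only free-boundary (6-connectivity) surface voxels can
realize the maximum, and among those only convex-hull vertices, so the
implementation reduces to an exact all-pairs maximum over hull vertices
(falling back to plain all-pairs for tiny or degenerate point sets). Voxel
centers, not faces, are used here; the bias is below one voxel diagonal.

**Rim surfaces and distances.** The outer surface is where CE meets
non-tumor (background or out-of-grid); the inner surface is where CE meets
the inner core; both under 6-connectivity. Surface points are, by default,
the midpoints of the separating voxel faces. A voxel-center convention
(points at the centers of the boundary CE voxels) is available in the
config, but it places both point sets half a voxel inside the true
interfaces and therefore under-measures every rim width by about one voxel —
enough to visibly bias `G_H` at 1 mm resolution (an even 10 mm rim measures
≈ 9 mm; a 5/10 mm two-mass rim measures `G_H ≈ 0.56` instead of 0.5). The
face convention is unbiased on the shell phantoms, which is why it is the
default. Minimal distances are computed in both directions (inner→outer and
outer→inner, each point to the nearest point of the opposite surface, via a
k-d tree that the tests verify against an exact all-pairs scan) and pooled
into one multiset; single-direction pooling is a config option.

**Geometric heterogeneity.** `G_H = (Q4 − Q3)/Q4` over the pooled distance
multiset, with `Q4` the sample maximum and `Q3` the linear-interpolation
(type-7) 75th percentile — the most widespread quantile default; the rule is
configurable. `G_H` is dimensionless and scale-invariant. For solid tumors
(no inner core) the rim distribution does not exist and `G_H` and the rim
quartiles are reported as missing rather than improvised from a centroid.

## Shell phantoms

The generator voxelizes (center-point membership, no partial volume) a
shell with inner radius `r`, outer radius `R1` everywhere except a spherical
cap around +z covering a solid-angle fraction `f` (cap half-angle from
`f = (1 − cos θ)/2`), where the outer radius is `R2`. The rim-width
distribution then has two masses: width `w1 = R1 − r` with probability
`1 − f` and `w2 = R2 − r` with probability `f`, so
`G_H = 1 − w1/w2` when `f < 0.25` and `0` when `f ≥ 0.25`, and
`δ_s = ((1−f) R1³ + f R2³)^(1/3) − r`. These closed forms are attached to
the phantom as ground-truth metadata.

An important regime restriction, found empirically and derivable from the
geometry: the two-mass prediction for `G_H` holds only for thin shells
(widths small against the inner radius). For strongly curved shells (e.g.
`r = 10 mm`, widths 5/10 mm) the *minimal* distance from inner-surface
points near the cap edge shortcuts laterally to the closer base outer
surface, and the cap's cliff wall contributes intermediate distances; the
measured `G_H` then falls well below the closed form (≈ 0.25–0.43). This is
a property of minimal-distance rim width itself, not of voxelization. The
default two-mass validation phantom therefore uses `r = 30 mm`, `w1 = 5`,
`w2 = 10`, `f = 0.2` at 1 mm isotropic, where the measured `G_H` is 0.500.

What the phantoms do **not** emulate: MRI noise, bias fields, partial-volume
mixing at boundaries, irregular (non-spherical) cores, multifocality.
Passing the phantom suite shows the geometric estimators are correct on
clean shell-shaped inputs at clinical resolutions; it does not validate
robustness to segmentation error.

## Texture

Intensities inside the ROI (whole tumor by default; CE-only as an option)
are min–max quantized into `N = 32` equal-width classes (the ROI maximum
maps to class `N`; a constant ROI collapses to one class). Pair and run
statistics pool the 13 unique 3D directions at Chebyshev distance 1. The
co-occurrence matrix counts both orderings of each in-ROI neighbor pair
(symmetric) and is normalized to unit mass. Runs are maximal collinear
same-class sequences, broken by the ROI boundary; the run-length matrix is
`N × M` with `M` the longest observed run, and `nr` is the total run count.
The 16 features follow the classical formula set; entropy uses the natural
logarithm with `0·ln 0 = 0`; run percentage is `nr / Σ_ij RLM(i,j)·j`
(runs per voxel-direction, in `(0, 1]`). One historical label quirk: the
feature with formula `1/(i²j²)` is implemented under its standard name
SRLGE (short-run low-gray-level emphasis). Conservation property used in
tests: `Σ_ij RLM(i,j)·j` equals (in-ROI voxels) × (directions).

## Survival analysis

**Units.** Days convert to months at 30.42 days/month — the only factor
consistent with the bundled cohort's printed day-scale extremes and its
month-scale summary (70/328/1592 days ↔ 2.30/10.78/52.33 months).

**Kaplan–Meier medians** use the midpoint convention (as in R's
`survfit`): the earliest time the curve falls to or below 0.5 and, when it
sits at exactly 0.5, the midpoint between that time and the next strict
drop. With no censoring this equals the ordinary sample median (e.g. all
events at {1,2,3,4} days → 2.5 days); the plateau-at-0.5-forever and
never-reaching-0.5 cases are reported missing. Curves come from lifelines.

**Log-rank** is the standard 1-df observed-minus-expected chi-square with
hypergeometric variance, implemented vectorized in-package because the
threshold scan and the Monte-Carlo calibrations evaluate it thousands of
times; it is validated against lifelines to 1e-10 in the tests.

**Cox regression** is the univariate proportional-hazards fit via
statsmodels `PHReg`, Breslow tie handling by default (Efron available),
with Wald 95% CI and p-value. Monotone partial likelihood (complete
separation in time) is flagged as non-converged rather than raised.

**Threshold scan.** Candidate cutpoints are midpoints between consecutive
sorted unique marker values; a candidate is admissible when both groups
hold at least `max(3, ⌈0.15 n⌉)` patients (the group-size floor is
configurable). The selected threshold minimizes a 3-candidate centered
moving average of the log-rank p-profile — the smallest smoothing that
rejects isolated single-threshold flukes while still finding genuine
low-p regions; ties break toward the smaller raw p, then the smaller
threshold. The full (threshold, p, smoothed p) profile is returned so the
selection is inspectable. Note the selected minimum-p split is
anti-conservative under the null (no multiplicity correction is applied,
matching the original analysis design); the per-split Cox HR and CI are
conditional on the selected threshold and inherit that optimism.

**Spearman correlations** (scipy, average ranks) carry interpretation
labels: |rho| < 0.1 "none", > 0.7 "strong", otherwise "intermediate".

## Cohort simulation

Markers are drawn from a named distribution (normal / lognormal / uniform);
survival is exponential with hazard `h0` below the true threshold and
`h0·HR` above it; censoring, when requested, is independent
`Uniform(0, T_max)` with `T_max` solved (bracketed root of the closed-form
expected censored fraction) to hit the requested rate. Everything is
reproducible from the spec's seed. Degenerate splits (all patients on one
side) warn but still return the cohort.

## Bundled cohort and the all-events assumption

The 40-patient table ships with the package exactly as published
(3-decimal `V_I` and `G_H`, integer survival days, missing MGMT entries
blank). It prints no censoring indicators, so the fixture marks every
observation as an event, with an `event` column available for override.
This assumption is validated by its consequences: the recomputed BVZ-arm
`G_H` split at 0.605 reproduces the published hazard ratio 3.931 and CI
(1.289, 11.985) to the printed precision, and the published per-split
"p-value" matches the log-rank p (0.011), not the Cox Wald p — both are
therefore reported per split. Quantities that would change under real
censoring are labeled approximate in the reference report. The recomputed
Spearman rho(V_I, G_H) is 0.519 against a published 0.522; the residual is
consistent with rounding of the published 3-decimal marker values.

## Problem sizes

Defaults keep the full suite and the acceptance script fast on one CPU:
shell phantoms at 1 mm (≈ 45³–105³ grids; 0.25–0.5 mm only where volume
convergence is being demonstrated), brute-force texture oracles on ≤ 6³
ROIs, Cox recovery over 200 replicates of n = 500, log-rank null
calibration over 1000 replicates of n = 200, threshold-scan recovery over
20 replicates of n = 200.

## Known limitations

- Segmentation is out of scope: the package starts from a 3-label mask and
  inherits its errors.
- `G_H` depends on resolution through surface sampling; values at spacings
  much coarser than the published ~0.7 mm in-plane / 2.5 mm slice regime
  should be compared with care.
- The texture convention (13-direction pooling, distance-1 offsets,
  min–max quantization per tumor) is one defensible choice among several
  used in the radiomics literature; absolute feature values are not
  comparable across conventions.
- The threshold scan's selected p-values are optimistic by construction;
  they should be treated as exploratory screening, as in the original
  study design.
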