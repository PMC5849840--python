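# Methods

## Problem and model

High mean dose to the parotid glands in head-and-neck radiotherapy causes
xerostomia; the sparing criterion used throughout this package is a mean
parotid dose (D_mean) at or below 26 Gy. A parotid is labelled *positive*
iff D_mean is **strictly** greater than 26 Gy — equality is negative, and
every downstream statistic (regression outcomes, ROC labels) uses that
convention.

The predictive quantity is purely geometric: the fractional overlap
OLV(P, T) = |P ∩ T| / |P| between the parotid P and a target T, computed
by voxel count on the structure grid, independent of any dose grid.
Targets are the per-level PTVs, their union (the combined PTV), and
millimetre expansions of both. The shipped decision rule is:

| scenario | gate | prediction |
|---|---|---|
| A | parotid overlaps high-dose PTV + 5 mm | positive iff OLV_HD05 > 0.083 (strict) |
| B | otherwise, overlaps an intermediate-dose PTV | positive iff OLV_IM ≥ 0.25 |
| C | otherwise, overlaps the low-dose PTV | negative |
| none | no overlap | negative |

Two grouping modes exist because the scenario-A gate can be read two ways:
`"expansion"` (the default; gate on the 5 mm-expanded high-dose PTV, the
form the threshold rule itself uses) and `"ptv"` (gate on the raw
high-dose PTV, the descriptive stratification). A scenario-B overlap
exactly at 0.25 is classified positive but flagged indeterminate in the
result note: the boundary is conservative by design for a toxicity screen.

Dose levels are ranked *within* a plan — highest prescription = "high",
lowest = "low", anything between = "intermediate". Published Gy bands for
the groups are ambiguous at 60 Gy, whereas relative rank resolves every
2-, 3- and 4-level prescription scheme unambiguously.

## Geometry conventions

* Regular grid, axis order (x, y, z), physical mm, 0-based indices; the
  center of voxel (i, j, k) is `origin + (i·sx, j·sy, k·sz)`.
* Contour rasterization: a voxel is occupied iff its **center** is inside
  an odd number of that slice's polygons (even–odd rule; same-slice
  polygons combine by XOR, so holes and islands are honored). Contour z
  snaps to the nearest slice within half a slice spacing; farther is an
  error. Center-point testing matches common treatment-planning-system
  behavior and makes volumes reproducible.
* Isotropic expansion: Euclidean distance transform with per-axis spacing,
  thresholded **inclusively** at the margin (occupied iff center-to-center
  distance to the structure ≤ margin mm). This is mm-true under
  anisotropic voxels; structuring-element dilation in voxel units is not.
  Expansion clips at the array edge and is not clipped to a body contour.
  Expanding a union equals the union of expansions for this operation, so
  the order of union and expansion is immaterial.
* Mean dose samples the dose at every occupied structure-voxel center;
  across grids it uses trilinear interpolation (exactly direct lookup on
  an identical grid), with no extrapolation — a structure voxel outside
  the dose grid is an error naming the voxel.
* Coverage V_d is the fraction of structure voxels with dose ≥ d
  (inclusive). The plan filter keeps V100% ≥ 0.90 — equality kept, since
  exclusion applies only below 90%. The clinical waiver for compromised
  coverage outside the GTV cannot be evaluated without GTV geometry and is
  recorded as such in the exclusion log.

## Statistics

* OLS with intercept; R² = 1 − RSS/TSS (0 when TSS = 0); two-sided slope
  t-tests. AIC uses the full Gaussian convention
  `n ln 2π + n ln(RSS/n) + n + 2(p + 2)`, counting σ as a parameter, so
  values agree with R's `AIC(lm(...))` (and equal statsmodels' AIC + 2).
  Only AIC *differences* matter for selection; the constant is fixed for
  testability.
* Backward stepwise deletion starts from the full model, removes the
  variable whose deletion lowers AIC most, stops when no deletion lowers
  AIC, never removes the intercept, and breaks exact AIC ties by removing
  the lexicographically last name — a fully deterministic path.
* ROC: candidate thresholds are −∞, midpoints between consecutive
  distinct scores, and +∞; prediction is positive iff score **>**
  threshold (strict, matching the rule's "greater than 0.083" form). AUC
  is the trapezoid over (1 − specificity, sensitivity), which equals the
  Mann–Whitney pair-ordering statistic with ties counted ½ (verified
  exactly in tests).
* Operating point: maximal Youden J = sensitivity + specificity − 1,
  operationalizing "best overall sensitivity and specificity"; J ties are
  resolved to the smallest threshold (highest sensitivity — conservative
  for screening).
* Calibration restricts to scenario-A records, sweeps OLV_HD05, and
  reports AUC for all five predictors side by side: the combined-target
  family on the full cohort, the high-dose family on the scenario-A
  subset (each on the population it is meant to discriminate; the two
  families are therefore not directly comparable numbers). Calibration
  returns a *new* config — the shipped default threshold is never
  silently overwritten. Both parotids of a patient enter as independent
  records; no clustering adjustment is applied.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
not anatomy. Per plan: two ellipsoidal parotids placed laterally
(volumes uniform over 11.35–55.18 cc, the clinical range; shape ratios
jittered around a 0.6 : 0.5 : 1 prolate form), one high-dose PTV ellipsoid
placed medially at a sampled lateral surface gap to the ipsilateral
parotid, and lower dose levels built as nested isotropic expansions.
Prescription schemes are drawn from ten published clinical combinations
(2–4 levels, 54–70 Gy) with their observed case-count weights. Dose is

```
D(x) = max over levels  Rx_level · exp(−dist_mm(x, PTV_level) / λ)
```

with λ = 5 mm by default: inside each PTV the dose equals its
prescription, outside it decays with distance at the steep gradient
characteristic of helical delivery (the ~0.5 cm effective field size is
exactly why the 5 mm expansion is expected to predict best — λ is a
parameter so that hypothesis is itself testable). Noise enters as one
Gaussian perturbation (sd 1.5 Gy) of each parotid's mean dose — the
cohort-level scatter the regression sees — rather than per-voxel noise,
which would be slow and would average out of D_mean anyway. Grids are
2 mm isotropic, 160×120×128 mm, sized so structures never touch the
boundary (touching is an error).

**Deliberate calibration.** The generator's defining condition is that the
noise-free D_mean = 26 Gy crossing falls at a requested OLV_HD05 (default
0.083). The free constant is the nesting margin between consecutive dose
levels: deeper nesting pushes the low-dose surface — and hence the
falloff dose — outward, warming the parotid at fixed overlap, so the
crossing moves monotonically with the margin. The margin is solved by
bisection against a 16-geometry pilot ensemble drawn from the same
distributions as the cohort (fixed internal seed): each pilot's personal
crossing is found by sweeping its parotid laterally across a fixed target
stack in whole-voxel steps (one dose computation per candidate margin)
and interpolating where its mean dose passes 26 Gy; the ensemble median
is driven to the requested crossing. A population-median calibration is
used rather than a single reference geometry because placement jitter and
the volume distribution make any single geometry systematically hotter or
colder than the cohort. The solve takes ~30 s and is cached per parameter
set; `level_margin_mm` can be set explicitly to skip it.

The nominal gap distribution (uniform on −12 to +10 mm) was chosen so
that roughly a third of parotids fall in scenario A and the scenario-A
subset straddles the tolerance crossing with both outcome classes well
represented — the regime in which threshold calibration is a meaningful
exercise. Remaining scatter at fixed overlap comes from parotid
size/shape variation, target placement jitter, per-step margin jitter
(±0.5 mm) and the prescription mix, which together produce
sensitivity/specificity in the 0.8–0.95 range at the recovered threshold
rather than a degenerate perfect split.

What the generator does **not** emulate: real parotid/target shapes,
inhomogeneous dose within targets, organ-specific falloff anisotropy,
inter-observer contouring variation, or any correlation between the two
parotids of one patient beyond sharing a target. Passing tests therefore
demonstrate correctness of the *pipeline* and internal consistency of the
*model*, not clinical accuracy on real cohorts.

## Problem sizes and tolerances

Tests run the pipeline at sizes chosen for fast, stable checks: geometry
oracles on 20×20×10 grids (100 random cases, exact array equality),
threshold recovery on a 100-plan cohort (±0.03 around the designed
crossing, sensitivity and specificity ≥ 0.75), the AUC-ordering check on
twenty 40-plan cohorts, and the shared unit-test cohort at 30 plans.
Regression identities are asserted at 1e-10, the AUC/Mann–Whitney
identity at 1e-12. The acceptance script uses 100 plans.

## Known limitations

* The stepwise selector, faithful to plain backward-AIC, retains a pure
  noise predictor whenever its t² exceeds ≈ 2, i.e. with probability
  ≈ 0.16 per predictor — exact recovery of a single true driver among
  noise happens in only ~70% of cohorts. This is a property of AIC
  selection itself, not of the implementation (the driver is always
  retained and the final model is always locally AIC-optimal).
* Bundle I/O uses an open NIfTI + JSON container; clinical DICOM
  RT-STRUCT/RT-DOSE import is out of scope (planar-contour rasterization
  is provided as the entry point an importer would target).
* No confidence intervals on AUC, no mixed-effects treatment of paired
  parotids, no EQD2/fractionation correction, no dose prediction in Gy —
  the model is a binary tolerance screen plus the regression comparisons.
* Ipsilateral and contralateral parotids are deliberately not
  distinguished: the model is purely overlap-based.
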