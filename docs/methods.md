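# Methods

## Geometry substrate

All metrics operate on a canonical representation: a simple,
counter-clockwise polygon with vertices in micrometers, image coordinate
convention (x right, y down, origin at the raster top-left, pixel centers
at integer + 0.5).

**Raster → polygon.** The largest connected foreground component is kept
(the FAZ is by definition a single avascular region; smaller components
are logged and dropped below `min_component_px = 10`), interior holes are
filled, and the boundary is traced as the 0.5 iso-contour of the component
after a light Gaussian smoothing (σ = 1 px). The smoothing matters:
tracing the binary staircase directly inflates the perimeter by ~5–6%,
which would corrupt every perimeter-based descriptor (circularity,
acircularity, convexity); with σ = 1 px the traced perimeter of a known
ellipse is accurate to ~0.3% while area stays accurate to ~0.1%. σ is a
parameter of `mask_to_polygon` for callers who want the raw contour.

**Pixel scale.** The default is 6000/1024 ≈ 5.859 µm/px: the nominal
6 × 6-mm en face field sampled at 1024², consistent with the annotation
threshold of 2.5 px ≈ 14.65 µm. The scale is configurable per image; no
axial-length magnification correction is applied.

**Moment-equivalent ellipse.** Second central moments of the polygon
*interior* are computed exactly via Green's-theorem formulas (region/filled
moment convention, as in standard particle analysis); axes are
`4·sqrt(eigenvalue)` of the covariance matrix. This is the "major axis"
used by roundness.

**Boundary resampling.** HD/CD operands are arc-length-uniform point
clouds (default 512 points per boundary). Sampling starts at the boundary
point whose direction from the centroid is nearest angle 0, making clouds
deterministic and comparable across re-runs. Ellipses are first
polygonized at 4096 points so the arc-length parameterization is exact to
well below the sampling interval.

## Classic descriptors

Computed from the µm-scaled polygon. Note `acircularity ≡ circularity^-1/2`;
both are reported because both are in common use. **Convexity convention:**
the ratio is reported as hull-perimeter / FAZ-perimeter, which is ≤ 1 and
decreases with boundary irregularity — the standard shape-analysis
convention. The reciprocal ("FAZ perimeter over hull perimeter") is
available via `convexity_convention="paper_printed"`; the two are exact
reciprocals and carry the same information.

## Inner ellipse

The fit maximizes ellipse area `π·a·b` over (cx, cy, log a, log b, θ)
subject to:

1. every one of `n_boundary_samples` (default 256) ellipse-boundary points
   lying inside the polygon (signed Euclidean distance ≥ 0), and
2. the polygon's geometric center lying strictly inside the ellipse.

Log-parameterized axes keep positivity unconstrained; SLSQP solves the
local problem; the non-convexity of irregular polygons is handled by
multi-start: the moment-equivalent ellipse shrunk by half, a
guaranteed-feasible inscribed circle at the centroid (radius 0.85 × the
centroid-to-boundary distance), plus seeded jittered variants, up to
`n_restarts` (default 8). Every candidate is re-verified on 2048 boundary
points; a candidate that exits the polygon by more than `tol_um`
(default 0.5 µm) is repaired by bisecting a shrink factor about its center,
and discarded if no shrink within 0.3× fits. Ties in area (symmetric
shapes such as squares admit a continuum of optima) are broken toward the
candidate whose center is closest to the centroid, for determinism.

When the centroid falls outside the polygon (extreme concavity, not
expected for a FAZ), the fit raises `CentroidOutsideError`; an explicit
opt-in (`allow_pole_fallback=True`) anchors the center constraint at the
pole of inaccessibility instead.

Against a brute-force grid search (center × axes × angle with exact
containment), the fit attains well over the grid optimum on random
star-convex polygons (the grid is necessarily coarse, so ratios > 1 are
expected); containment violations stay below 0.5 µm.

**diff iE** is `|A_FAZ − A_iE|`; by containment this equals the dropout
excess area. Whether the original "absolute inner-ellipse difference" was
an area difference is not fully determined by its name; area is the
interpretation consistent with the iE being a healthy-FAZ area proxy, and
is what is implemented.

## Boundary distances

`hausdorff` is the max of the two directed Hausdorff distances; `chamfer`
averages squared nearest-point distances. The Chamfer reduction across
directions is configurable — `mean_of_directions` (default; symmetric,
units stay µm²), `sum_of_directions` (as in common point-cloud learning
implementations), or `forward_only` — because published definitions vary;
all three are monotone-equivalent. Distances are computed in physical µm
(HD) and µm² (CD); no pixel-power normalizations are applied. Nearest
neighbours use exact pairwise evaluation for small clouds and a KD-tree
above ~10⁶ pairs; both paths are tested against brute force to 1e-9.

## Gensini scoring

`severity_points` (25% → 1, 50% → 2, 75% → 4, 90% → 8, 99% → 16,
100% → 32) and `segment_multipliers` (left main ×5, proximal LAD/LCx ×2.5,
mid LAD ×1.5, …, Ramus intermedius ×1) ship as JSON config transcribed
from the original Gensini scheme and can be replaced per study. Off-table
stenosis percentages snap to the nearest category with a warning. Group
cut-offs: ternary 0: GS ≤ 3, 1: 3 < GS ≤ 31, 2: GS > 31; binary 0: GS ≤ 3,
1: GS > 14, with (3, 14] an explicit excluded band (mere coronary
sclerosis). "GS 4 to 31" is read as (3, 31] so the ternary groups are
exhaustive for real-valued scores; scores are kept real-valued.

## Synthetic generator

A shape is a base ellipse (defaults 330 × 270 µm semi-axes — a ~0.28 mm²
FAZ, typical for adults on a superficial-plexus slab) plus `n_notches`
outward radial raised-cosine bumps at seeded non-overlapping random
angles, plus smooth low-order Fourier boundary noise (σ = 2 µm) clipped so
the base ellipse is always contained. Dropout is outward-only because
capillary loss enlarges the avascular zone; this is what makes the base
ellipse a lower bound for the true inscribed ellipse and gives the family
analytic truth: the planned excess area of the bumps is integrated by
dense quadrature of the exact polar integrand and stored in the truth
sidecar.

The cohort generator draws a Gensini score per patient from a zero-inflated
Poisson (p_zero = 73/212 ≈ 0.344 — the CAD-free fraction of a cardiology
admission cohort; diseased mean 30, placing patients across the moderate
and severe groups), maps GS monotonically to notch count (1–6) and depth
(8 + 0.9·GS µm, capped at 120 µm), attenuates right eyes by ×0.6 (the
left-eye effect is stronger, consistent with the left carotid's direct
aortic branching), and drifts age, male fraction and diabetes prevalence
upward with severity. The GS→depth slope and the laterality factor are
order-of-magnitude modeling choices — no published effect sizes exist for
this mapping — and are config fields, not claims about real anatomy.

What the generator does *not* emulate: OCT-A speckle and texture,
projection artifacts, segmentation-threshold variability, inward boundary
defects, or any correlation structure between the two eyes beyond the
laterality factor. Tests passing on this family therefore establish that
the machinery responds correctly to controlled dropout-like deformation,
not that the biomarkers separate clinical groups at any particular AUC.

## Cohort statistics

- **Group tests**: Shapiro–Wilk on every group and Levene's test gate the
  pathway (α = 0.05): ANOVA + Tukey HSD if parametric assumptions hold,
  else Kruskal–Wallis + Dunn's test with Holm correction (Dunn implemented
  directly from the pooled ranks with tie correction). A Bonferroni factor
  multiplies the pairwise adjusted p-values when several metrics form one
  family.
- **ZIP effect model**: the GS (rounded to an integer count) is regressed
  on one metric + age + sex + diabetes in both the Poisson-count and the
  logit structural-zero part (statsmodels `ZeroInflatedPoisson`, BFGS).
  Continuous predictors are standardized internally for stability; with no
  zeros in the outcome the model degrades to plain Poisson with a warning.
- **Prediction**: stratified fivefold CV; SMOTE (k = 5, implemented
  directly as minority-class k-NN interpolation) is applied to the
  training folds only — `CvResult.fold_details` exposes the original-row
  indices of every test fold so the no-leakage property is structurally
  assertable. Binary task: logistic regression, ROC AUC. Ternary task:
  ordinal logistic — default cumulative-logit (proportional odds,
  statsmodels `OrderedModel`); an `immediate_threshold` variant is provided
  as a chain of conditional binary logits P(Y = j | Y ≥ j) — and macro
  one-vs-rest AUC. The 95% interval on the AUC is a t-interval over the
  five fold values; fold dispersion is the only uncertainty source used.
- **Agreement**: Dice and Jaccard on rasterized masks (identical frames
  required; `dice = 2J/(1+J)` holds identically), Bland–Altman bias ±
  1.96·SD limits of agreement on paired per-eye metric values.

## Numerical choices and degenerate inputs

- Polygons are normalized to CCW at construction; a repeated closing
  vertex is dropped; < 3 distinct vertices raise `InvalidPolygonError`.
- Containment tolerance 0.5 µm ≈ 1/12 px at the default scale — far below
  annotation uncertainty.
- Batch pipelines (cohort generation) default to 2 restarts and 64
  containment samples, which on the synthetic family reproduces the
  full-setting fit to well within the biomarker noise; per-image runs use
  the full 8 restarts.
- Problem sizes in the test-suite simulations (e.g., 50 seeds per notch
  depth, 200 ZIP replicates at n = 1000, cohorts of 60–500 patients) were
  chosen to make the Monte-Carlo bands comfortably tighter than the
  asserted tolerances at desk scale.
- Degenerate cases raise typed errors (`NoForegroundError`,
  `CentroidOutsideError`, `FitFailedError`, `DataError`, `SpecError`)
  rather than returning sentinel values; the file-level pipeline isolates
  per-file failures and fails only if every input fails.

## Known limitations

- The inner-ellipse fit is a local optimizer with multi-start, not an
  exact global method; on adversarial (deeply non-star-convex) polygons it
  can undershoot the true optimum. The grid-oracle test bounds this on the
  shape family of interest.
- The containment constraint is enforced on a finite boundary sample; an
  ellipse could in principle exit the polygon between verification
  samples, by an amount bounded by the local curvature and the 2048-point
  verification spacing (sub-µm for FAZ-scale shapes).
- Clinical AUCs from patient cohorts are not reproducible here — the study
  imagery is not public; the statistics stage is validated on simulated
  data only (parameter recovery, null calibration, separability, leakage
  guards).
- GeoJSON input assumes QuPath's image-convention coordinates in pixels;
  files already in physical units need `pixel_size_um = 1`.
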