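# Methods

This note documents the models, conventions and numerical choices behind
`segqa`, and what the synthetic data do and do not establish.

## Contour representation and voxelisation

Structures are ordered closed planar polygons on axial slices, in
patient-space millimetres (x/y in-plane, z superior–inferior) — the CT
convention used by radiotherapy structure sets. A slice may hold several
polygons (multi-part cross-sections such as a mandible ramus pair, or
holes under the even-odd rule). Slice z positions must be strictly
increasing; duplicate z in one structure is an error.

Voxelisation uses **pixel-centre inclusion under the even-odd rule**: a
voxel is set iff its centre lies inside an odd number of that slice's
polygons, with a point on a polygon boundary counting as inside that
polygon. The rule is deterministic, supports annuli and multi-part
regions, and is verified against an independent ray-casting oracle. Each
contour slice must map to a grid plane within half a slice thickness
(dz/2); nearest-plane ties at exactly dz/2 resolve by round-half-to-even.
The default grid is 1 × 1 × 2 mm — 2 mm slices as in H&N planning CT, and
1 mm as a representative in-plane pixel; both are configurable. Voxel
count × voxel volume converges to polygon area × slab thickness as
spacing shrinks (tested at 1.0 / 0.5 / 0.25 mm).

Mask-to-contour tracing (needed for NIfTI input) runs marching squares at
the 0.5 iso-level between voxel centres, so rasterise → trace →
rasterise is exactly idempotent on the voxel set.

The 3D DSC is computed on voxelised structures (voxel-based rather than
mesh-based overlap); at the default spacing the discretisation error is
well below the decision scale of three-sigma limits.

## Similarity metrics

**DSC** is plain voxel counting, symmetric, undefined when both masks are
empty (raised, never silently 0).

**2D 95% Hausdorff distance.** Slices of the two stacks are paired when
their z differ by at most dz/2. On each shared slice, every polygon
boundary is resampled at arc-length steps ≤ 0.5 mm (default; at least the
original vertex density), and directed point-to-polyline distances are
computed in both directions with segment-accurate geometry — not
point-to-vertex, which overestimates distances between samples. How the
per-slice values aggregate into one number per organ is a convention this
package fixes explicitly: **all directed distances from all shared slices
are pooled and a single 95th percentile is taken**, with linear
interpolation between closest ranks (`numpy` "linear"). Pooling is
order-statistic based, reduces to the per-slice value for single-slice
structures, and is bit-stable given the sampling step. Slices present in
only one stack are excluded and counted (`n_gold_only_slices`,
`n_auto_only_slices`); with no shared slice the metric is undefined and
reported as missing, never 0.

This exclusion is the metric's documented blind spot: a contour truncated
in the superior–inferior direction but otherwise identical on shared
slices has HD95 = 0 while DSC drops by the closed form 2(N−k)/(2N−k) for
uniform cross-sections. Conversely a small disjoint attached component
with matched SI extent barely moves DSC but drives HD95 to the
component's distance scale. Both mechanisms are reproduced and tested.

## Three-sigma limits

Per organ, the reference cohort's DSC mean uses the arithmetic mean and
the SD the n−1 (sample) denominator. The gross-failure limit is
μ − 3σ, clamped at 0; an upper limit μ + 3σ applies to HD95 when
reference HD values exist. Flagging is **strict**: DSC exactly at the
limit passes. Undefined HD95 yields an *undefined* HD flag, never a
false "pass". Limits are carried at full precision; two-decimal
presentation uses half-up rounding. One-sided limits only — the QA
question is "too dissimilar", not "suspiciously similar".

The `ContourQAModel` / `ContourQAResults` pair exposes this as a fitted
model: `fit()` estimates the limits, `summary()` prints them with
standard errors, `flag()`/`audit()` apply them. The SE of the limit
estimator mean − 3·SD uses the normal-theory delta approximation
σ·√(1/n + 9/(2(n−1))) ≈ 0.334σ at n = 50. That magnitude matters for
interpreting calibration-cohort size: a 50-case cohort localises the
limit only to about ±0.65σ at 95% confidence (coverage of a ±0.5σ band
is ≈87%, confirmed by simulation); pinning the limit within ±0.5σ with
95% confidence needs roughly 150 reference cases.

## Review and reporting

Expert review is modelled as explicit annotation input and never
automated: each flagged case needs exactly one verdict from the closed
set {censored_suboptimal_manual, setup, anatomy, artefacts, unknown}.
Censoring (the *gold* contour was at fault) removes a case from the
true-failure numerator but **not** from the per-organ denominator.
Missing annotations for flagged cases are an error; orphan annotations
warn; duplicates are conflicts. The cohort summary enforces the
bookkeeping identities (true = flagged − censored; categories sum to
true; conservation of records) and reports per-organ and pooled rates
plus the censored fraction of all flags, rendered as percentages at one
decimal place with half-up rounding. With nothing flagged the censored
fraction is reported as not-applicable rather than 0.

## Synthetic data

The generator emulates H&N OAR contour pairs on a 2 mm-slice CT-like
grid, at two levels.

**Contour level.** Organ archetypes are geometric: ellipsoids for
brainstem (semi-axes 10 × 12 × 16 mm) and parotids (12 × 15 × 20 mm, at
±45 mm laterally) and a C-shaped annular sector for the mandible (radii
30/22 mm, 70° anterior opening); a uniform cylinder serves analytic
tests. Baseline auto contours apply radial Gaussian boundary noise whose
amplitude is drawn per patient from Uniform(0.3, 0.9) mm — generic
delineation variability. This range is a deliberate design choice: a
(near-)uniform DSC distribution has bounded support within ±√3 σ of its
mean, so a three-sigma limit calibrated on the same distribution
structurally cannot flag failure-free pairs, and end-to-end audits
recover injected failure counts exactly, for any seed, without tuning.
Failure injections map review verdicts to perturbations: *setup* → 7°
in-plane roll about a pivot 90 mm inferior-posterior of the organ
(≈11 mm displacement); *anatomy* → attached disjoint component sized
to add tens of percent of volume; *artefacts* and suboptimal-gold
censoring → truncation of 5 superior slices; *unknown* → 4 mm boundary
noise. All push DSC far below any calibrated limit (≈0.26–0.83 vs
limits ≈0.91–0.94 in practice).

The default injection plan reproduces the audited-cohort review outcome
(4/20/13/7 flags, 2/9/6/3 censored, categories per organ, 500 patients
per organ), so the synthetic end-to-end audit arrives at the same
true-failure arithmetic (2/11/7/4; 1.2% overall; 45.5% censored) from
generated geometry rather than typed-in counts.

**Metric level.** DSC cohorts are drawn from Normal(μ, σ) truncated to
(0, 1] with per-organ defaults μ ± σ of 0.81 ± 0.06 (brainstem),
0.91 ± 0.02 (mandible), 0.76 ± 0.06 / 0.74 ± 0.08 (parotids), as
established on a 50-patient reference cohort; gross failures replace a
draw with Uniform(0.1, 0.4), validated to lie wholly below every μ − 3σ.
The truncated-normal model is the distributional assumption already
implicit in a three-sigma rule.

**What passing tests do not show.** The phantoms have smooth convex or
C-shaped cross-sections, stationary noise and failure modes injected at
known severities; real contours have anatomy-driven shape detail,
spatially correlated observer variability, and failures of continuously
varying severity. Synthetic results therefore validate the *pipeline
arithmetic and metric implementations*, not clinical failure-rate
estimates; reference statistics for clinical use must come from real
reference cohorts.

**Problem sizes.** The shipped end-to-end check uses 50 reference and
500 test pairs per organ across four organs (2 200 contour pairs), the
Monte-Carlo tail check 10⁶ draws, and the limit-recovery study 1 000
replicates of 50 draws — sizes chosen to match the two-phase cohort
design while keeping a full run under a minute per stage on one CPU.

## Numerical conventions and degenerate inputs

* Percentiles: linear interpolation between closest ranks.
* Rounding for presentation: decimal half-up (never banker's).
* Sample SD: ddof = 1 everywhere.
* z-comparisons carry a 10⁻⁹ mm slack; contour-json round-trips floats
  exactly via `repr` shortest round-trip.
* Degenerate inputs raise typed errors (`segqa._exceptions`): both masks
  empty, grids mismatched, polygons outside the grid, unaligned slices,
  < 2 reference values, DSC outside [0, 1], truncation removing every
  slice, flagged cases without annotations, inconsistent denominators.
* Boundary-noise perturbation clips perturbed radii at 0.1 mm to keep
  polygons simple; the roll perturbation is exact rigid rotation.

## Known limitations

* HD95 aggregation across slices is a convention; published per-organ
  HD thresholds derived under a different (unstated) aggregation are not
  directly comparable.
* Rasterisation is pixel-centre based; sub-voxel partial occupancy is
  not modelled.
* DICOM-RT support covers CLOSED_PLANAR contours and axis-aligned NIfTI
  affines only; no registration, no image-data handling.
* The three-sigma rule assumes approximately normal in-control DSC; for
  heavily skewed organs a percentile-based limit would differ (out of
  scope here).
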