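# Methods

This note documents the models, calibrations and design choices behind
hydromorph, in the order the measurement chain runs.

## Volumes and distances

All imaging operates on 3D scalar grids with millimetre voxel spacing
(NIfTI convention: 0-based voxel indices, world coordinates are
voxel-centre positions under the affine).  Every distance the package
reports is physical (mm).  The Euclidean distance transform (EDT) is
spacing-aware (`scipy.ndimage.distance_transform_edt` with `sampling`),
measuring from each object voxel centre to the nearest background voxel
centre; all distances therefore scale linearly with spacing, which the
tests assert.

## Skeletonization

The CSF compartments of interest are *sheets* (the subarachnoid shell,
the interhemispheric fissure, sulci), and standard curve-thinning
algorithms erode sheets completely: a free-standing 20×20×3 slab thins
to zero voxels under the usual 3D medial-axis thinning, and a fissure
fin attached to the CSF shell vanishes the same way.  hydromorph
therefore implements its own topology-preserving thinning:

- only **simple points** are deleted (exactly one 26-connected object
  component among the 26 neighbours and one 6-connected background
  component in the 18-neighbourhood touching the centre), so homotopy —
  in particular the connected-component count — is preserved exactly;
- deletion is sequential in increasing distance-to-background order
  (distance-ordered homotopic thinning), which erodes from the surface
  inward and makes the result nearly equivariant under grid rotations;
- **medial anchors** are never deleted: voxels whose EDT equals the
  26-neighbourhood maximum *and* that sit on a strict descent across the
  structure (some axis whose two neighbours are both object voxels with
  a smaller minimum EDT).  Flat medial plateaus are anchored whole, so
  slab and shell medial surfaces survive; boundary plateaus (e.g. a
  2×2 bar, which should thin to a line) are not anchored;
- curve endpoints (≤ 1 object neighbour) are kept, so tube centerlines
  run cap to cap.

The result is one voxel thick transverse to each local medial structure
(an even-thickness slab can keep a two-voxel medial plate, consistent
with the width tolerance below).  Structures thinner than ~3 voxels
across have no interior anchor layer and may thin to curves; the phantom
defaults keep all sheet widths ≥ 3 mm at 1 mm spacing.

## Width calibration

Local width at a skeleton voxel is `w = 2·d − s/2` (EDT value `d`, mean
spacing `s`), floored at one voxel.  Rationale: the centre-to-centre EDT
overestimates the continuous half-thickness by up to `s/2` when the
nearest background lies along a grid axis, but by roughly nothing when
it lies diagonally, which is the prevailing case on curved or oblique
sheets (and for tubes whose axis sits at a random sub-voxel offset).
Subtracting a quarter voxel per side splits the difference: an odd
axis-aligned slab reads high by `s/2`, an oblique sheet low by about
`s/2`, bounding the error near half a voxel in both regimes.  A
full-voxel correction (`2·(d − s/2)`) is exact for axis-aligned slabs
but under-reads curved shells by more than a voxel, which is why it was
not used.  Slab phantoms of thickness 3–10 mm at 1 mm spacing are
recovered within ±1 mm (asserted), as are the frontal-SAS shell and IHF
slab of the head phantom.

Regional statistics (mean/max width) are computed over skeleton voxels
inside the ROI — not over a projected surface — and this choice is
echoed in the report metadata.  The frontal-SAS and IHF ROIs are always
*inputs*: on real data they are drawn manually, and the phantom
generator emits compact interior ROI patches that stay clear of sector
seams, shell junctions and sheet rims, where medial width is undefined.

## Skeleton subdivision

Skeleton voxels at most 6.0 mm below the outer surface of the
skull-peeled total mask (its own EDT) are SAS; deeper voxels are sulcal.
The 6 mm default follows the reported 95th-percentile SAS width in
healthy infants; the boundary value itself classifies as SAS (inclusive
reading of the cut-off).  The threshold is configurable.

## Optic-nerve morphometry

Segmentation inside the rough per-nerve ROI is an intensity window
followed by restriction to the largest connected object.  The published
description says "8-connected object", which is 2D vocabulary; 3D
26-connectivity is used here (the stacked-slice generalization) and
recorded as such.  Segmentation thresholds are explicit inputs; the
phantom defaults put them halfway between the background/tissue and
tissue/CSF levels.

The centerline is the maximum-arc-length geodesic between skeleton
endpoints (Dijkstra between degree-1 voxels; ties broken by the
lexicographically smallest endpoint pair; for endpoint-free cycles, the
longest shortest path over all voxel pairs).  Tip voxels whose EDT falls
to a single voxel are spurs into the tube end caps and are trimmed.

- **Length** is the arc length of a cubic smoothing spline through the
  path (chord-length parametrized, residual budget 0.25·s² per point).
  The budget absorbs the half-voxel staircase quantization of voxel
  paths — which otherwise inflates arc length by up to ~8% on oblique
  runs — while genuine curvature at anatomical wavelengths (≥ ~10 mm)
  costs far more residual than the budget allows and is preserved.
- **Width** is the mean of `2·d − s/2` along the centerline with the
  first and last two voxels excluded (the EDT is biased at tube ends).
  The mean — not the maximum — is used because "nerve width" is read as
  a caliber; this is stated in the report metadata.
- **Tortuosity** is the arch-to-chord ratio of the smoothed centerline
  (≥ 1, equal to 1 iff straight), min–max normalized to a 0–1 index
  within the analyzed cohort.  Indices are not comparable across
  cohorts; the cohort size used enters the report metadata.

Both nerves are measured and averaged per subject; a missing side falls
back to the present side with a logged flag.

Validated tolerances (asserted in the tests): straight tubes read
length within ±1 mm and ratio 1.00 ± 0.02; a semicircular tube reads
the ratio within 5% of π/2; over 20 random sinusoidal nerves the median
length error is ≤ 5% and the median width error ≤ 1 mm; 90° grid
rotations change length/width/ratio by < 3%.

## Accessory measurements

Region growing uses a fixed similarity reference — the mean seed
intensity — so the result is deterministic, independent of visiting
order, and monotone in the tolerance; growth is 26-connected.  The
lateral-ventricle split plane sits at the midpoint of the mask's
bounding extent along the configured axis; a slice exactly on the plane
is shared half-half so the compartments always sum to the total.
Meckel's-cave volumetry is provided but feeds no downstream statistic.

## Cohort statistics

- **Z-scores** use *maximal* regional widths against a normative table
  of per-measure, per-age-bracket means and SDs.  A space is enlarged
  iff `z > 1.96` strictly (the boundary value is not enlarged).  The
  shipped normative table is a documented fixture: the original
  normative sample (n = 150 healthy infants) is not available in
  machine-readable form, so the fixture values are chosen to make the
  simulator's enlarged group typically exceed the threshold (see below).
- **Abnormality score** = number of enlarged spaces (0–2); ≥ 1 defines
  the "quantified" enlargement group.
- **Comparisons**: Student's t, Mann-Whitney U (tie-corrected), Pearson
  χ² without continuity correction, and Fisher's exact test; the method
  is always caller-chosen, never switched silently.  Fisher's exact
  test, being conditionally exact, is *conservative* on discrete 2×2
  tables: at 30 subjects per group its true size is ≈ 0.03 and cannot
  reach the nominal 0.05; the calibration test records this fact.
- **Regression**: candidates with pairwise |r| > 0.7 are pruned (the
  later-listed member of a pair is dropped — deterministic), then OLS
  with backward elimination (drop the largest-p predictor while
  p > p-to-remove; default 0.10, configurable).
- **ROC**: AUC as the Mann-Whitney concordance probability (ties count
  ½), p-value from the same U statistic; multi-marker models are scored
  by logistic predicted probabilities, with a lightly ridge-penalized
  fallback under complete separation (the penalty only needs to keep the
  subject *ranking* defined).
- **OR/RR**: logistic odds ratios with Wald CIs (non-convergence under
  separation raises instead of returning a silently huge OR); risk
  ratios with the log-normal CI, 0.5 continuity correction on all four
  cells when an event cell is zero (flagged).
- **Two-step clustering** reimplements the published TwoStep scheme's
  modelling assumptions without cloning any proprietary implementation:
  features are standardized; step 1 assigns subjects sequentially to
  sub-clusters under the Gaussian log-likelihood merge distance
  ξ(v) = −N_v Σ_k ½·ln(σ̂_k² + σ̂_vk²) (overall per-feature variance as
  regularizer), opening a new sub-cluster when the distance exceeds an
  adaptive threshold that doubles whenever the sub-cluster count passes
  50; step 2 merges agglomeratively under the same distance; the number
  of clusters in 1..max_k minimizes BIC = −2Σξ + 2·d·k·ln N.  The
  procedure is deterministic given the input order; at 6 SD separation
  relabeling the input permutes the labels without changing the
  partition.  Default clustering features are the five measures that
  differ between the risk subgroups: frontal-SAS mean width, IHF mean
  width, ON width, ON length, ON tortuosity index.
- **Risk stratification** crosses the cluster with the highest event
  rate against the rest in a 2×2 table and reports the RR with CI plus
  per-cluster feature means and Mann-Whitney contrasts.

## Synthetic data

The head phantom places a brain ellipsoid (default semiaxes 30/34/27 mm)
in a 96³ grid at isotropic 1 mm spacing and builds the CSF shell as a
constant-thickness offset band of the brain surface (2 mm base,
thickened in the anterior sector to the frontal-SAS parameter), an IHF
slab, coronal sulcal invaginations, two sinusoidal ON tubes in free
space, Meckel spheres and a posterior venous-sinus tube.  Ground truth
(widths, quadrature arc lengths, arch-to-chord ratios, volumes) comes
from the continuous generating geometry, not the voxelization.  Tube
centerline curvature is validated against the tube radius
(λ² ≥ 4π²·a·r), since a tube that swallows its own bends has no
well-defined centerline.  Intensities are three levels (CSF-bright,
tissue, background) plus optional Gaussian noise; anisotropic spacing is
supported but not default.

The cohort simulator draws a two-group sample (default 34 subjects,
23/34 enlarged — the published cohort scale).  Group shifts are effect
sizes in SD units with baselines fixed as documented fixtures: ON width
3.12 ± 1.0 mm shifted +1.44 SD, length 10.84 ± 3.5 mm shifted +1.66 SD,
tortuosity ratio 1.15 ± 0.05 shifted −2.0 SD, frontal-SAS/IHF mean
widths 1.94/1.88 ± 0.6 mm shifted +3.05/+2.70 SD — magnitudes chosen to
reproduce the reported subgroup means (e.g. ON width 4.56 vs 3.12 mm).
Maximal widths are the means plus a 1.0 ± 0.2 mm offset.  Complications
are Bernoulli with baseline probability 0.073 and a planted risk ratio
(default 7.28) for the joint "enlarged CSF + deformed ON" pattern — not
for enlargement alone, mirroring the finding that enlargement by itself
carried no excess risk while the joint cluster did.  Age and sex are
nuisance covariates independent of group (an optional age slope on ON
length supports age-adjustment tests).  With all effect sizes zero, the
group-comparison p-values are uniform (asserted by a KS test over 500
null cohorts).

What the simulator does **not** emulate: cortical folding, skull/scalp,
MR physics and artifacts, realistic age dependence of head geometry, or
the real normative distribution of CSF widths.  Passing tests therefore
demonstrate correctness of the measurement and statistics chain under
controlled geometry and planted effects — not clinical performance on
real scans, and the real cohort's published AUC/OR/RR values are not
reproduction targets (no data were deposited).

## Problem sizes and numerics

Default grids are 96³ (head phantoms) and ≤ 46³ (tube fixtures); the
calibration suites use 2000 null cohorts of 30 per group, 400 logistic
replicates of n = 2000, risk-ratio recovery at n = 5000, and 100
simulated 34-subject cohorts — sizes at which every Monte-Carlo check in
the tests is stable at its stated tolerance.  Dijkstra ties break to the
lexicographically smallest endpoint pair; cluster merges break ties by
first-found minimum distance; all simulators take explicit seeds and are
bit-reproducible.

## Known limitations

- The thinning is sequential and therefore only *approximately*
  rotation-equivariant (plateau tie resolution depends on scan order);
  measured metrics vary < 3% under 90° rotations on well-resolved tubes.
- Width estimates carry the ±half-voxel calibration bias described
  above; sheets thinner than ~2 voxels read as one voxel wide.
- Tortuosity recovery degrades when the bend curvature radius approaches
  the tube radius (the generator rejects such geometry), and the
  smoothing spline attenuates oscillation wavelengths shorter than
  ~8 mm at 1 mm spacing.
- The ON width definition (mean caliber) and the 26-connectivity reading
  of the segmentation rule are stated choices where the published
  description is ambiguous.
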