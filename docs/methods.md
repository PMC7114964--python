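# Methods

## Conventions and data model

Elevation is stored up-positive, so seabed depths are negative numbers; all
"water depth" attributes are reported as positive metres by negation at the
description layer. This keeps the sign of the bathymetric positioning index
intuitive: positive BPI = shallower than the surroundings. Rasters are
square-celled, row 0 northernmost; the grid origin is the outer corner of
the top-left cell. Nodata cells are NaN plus an explicit mask and propagate
through every derivative.

## Focal statistics and terrain derivatives

*Annulus membership* uses Euclidean centre-to-centre distance in cell units
with inclusive bounds (inner ≤ d ≤ outer). GIS packages discretise annuli in
undocumented ways; the inclusive Euclidean rule is exactly reproducible and
is what the brute-force test oracles implement. Cells outside the raster or
under the nodata mask do not contribute; an output cell becomes nodata when
fewer than `min_valid_fraction` (default 0.5) of its annulus members are
valid. The sliding sum is an exact windowed correlation on small problems
and switches to FFT convolution above ~2·10⁸ multiply-adds; the switch
changes results by ≲1e-10 m on metre-scale elevations, which is inside the
1e-9 equivalence the tests assert.

*Slope* is Horn's 3×3 estimator in decimal degrees — the default of the
major GIS packages, which the original workflow ran. Nodata neighbours are
replaced by the centre value, edges by replication, so border cells
under-estimate gradients and tests evaluate interior cells.

*Rugosity* has two printed definitions in circulation: the standard
deviation of slope, and the 3D/planar surface-area ratio, both over a 3×3
window. Both are implemented; `sd_of_slope` is the default used by the
description stage. The focal SD is population SD over complete (9-cell)
windows, computed two-pass (window mean subtracted before squaring) because
the one-pass moment form loses half the significant digits on near-constant
slope fields and visibly fails the "zero on a plane" limit. The
surface-area ratio triangulates the centre cell against the eight
half-distance midpoints; it is exactly 1 on a horizontal plane and sec θ on
a plane of slope θ.

## BPI and delineation

BPI = z − annulus mean of z; no standardisation is applied, because the
delineation thresholds are calibrated in raw BPI units. Default annulus
i8 × o24 (16–48 m at 2-m cells), matched to mound widths and spacing of the
target setting; both radii are configurable.

Delineation thresholds (defaults: cutline 3, minimum peak BPI 3.5, minimum
area 50 m², minimum width/length 0.2, buffer 4 m) are applied to the RAW
pre-buffer region: the buffer exists to compensate for the cutline contour
sitting on the flanks rather than the base, i.e. it is cosmetic expansion,
not part of selection. Thresholding is inclusive (BPI ≥ cutline). Regions
grow 8-connected so a mound whose summit cells touch diagonally stays one
feature. Width/length comes from the minimum-AREA rotated bounding
rectangle (width = shorter side); orientation is the azimuth of the long
axis, clockwise from grid north in [0, 180), 0 for a square tie. Buffering
uses round joins. Overlapping buffered outlines are flagged `merged_flag`
and kept separate: merges of adjacent mounds are resolved by manual editing
downstream, and dissolving them automatically would silently manufacture
the artefact that editing exists to correct.

## Feature description

Zonal membership is cell-centre-inside-outline (even-odd rule), the common
zonal-statistics convention; attributes are measured on the buffered
outline, since the description stage exists to *re*-measure features after
buffering and manual edits. Water-depth statistics are negated elevations.
`ConfCL_WD` is the depth of the deepest contour (default spacing 0.5 m)
that closes entirely inside the outline and encloses the summit cell,
found by marching-squares contouring of the DEM window; when no contour
qualifies (e.g. a feature open to one side) it is NaN and so is
`MinVRelief`. Relief follows the profile geometry: `MaxVRelief` =
MaxWD − MinWD and `MinVRelief` = ConfCL_WD − MinWD; these formulae are this
package's reading of the sketch-level definition (the defining equations
are not printed anywhere authoritative).

The *initial slope* reconstructs the pre-mound seabed: cells under the
outline are voided and refilled as the harmonic (Laplace) solution with the
surrounding cells as Dirichlet boundary, then the Horn slope of the
reconstruction is averaged over the voided cells. The linear system is
solved exactly with a sparse direct factorisation rather than by Jacobi
sweeps — same fixed point, no iteration-tolerance parameter, and a linear
seabed is reproduced exactly up to discretisation. Caveat: when the outline
is the delineated polygon, the boundary still carries ~1 m of residual
mound skirt, which biases the reconstructed slope upward by a few tenths of
a degree; recovery tests therefore evaluate the operator on outlines that
cover the full planted skirt.

Current speed is joined as the value of the (typically 100-m) current
raster cell containing the feature centroid — a deliberate nearest-cell
join, mirroring attribute joins in GIS practice, since the current model is
two orders of magnitude coarser than the features. Coral cover is the area
fraction of the outline intersected with the union of (repaired) coral
polygons; classes are left-exclusive/right-inclusive bins, so exactly 50%
falls in ]25;50].

## Habitat model

Mounds are the samples. Candidate predictors are the full attribute set
plus joined current speed; groups of predictors with pairwise r² > 0.95
(connected components of the high-correlation graph) are reduced to the
member with the largest between-class variance fraction against the
response — on real mounds this collapses the four near-duplicate depth
variables to maximum water depth. The forest uses 1500 trees and 6
candidate variables per split. The phrase "leaving one-third out" in the
source description is ambiguous; it is resolved as the standard reading:
two-thirds train (stratified by class), one-third held out. Out-of-bag
statistics are reported for the training partition; sensitivity,
specificity (0.5 vote threshold) and AUC for the holdout. AUC is the
Mann-Whitney rank statistic with ties counted half; the tests verify it
against a literal pairwise count. Importance is permutation mean decrease
in accuracy (10 shuffles per predictor on the holdout) — the quantity the
original analysis plots — not impurity decrease, which is biased toward
continuous predictors. Response curves are partial dependence on a
25-point grid spanning each predictor's observed range. Fixing the seed
fixes the split, the forest, the permutations and hence every reported
number.

## Synthetic scenes

The generator emulates the target setting: a 2-m grid (default 700 × 1000
cells), a gently sloping seabed around 190 m depth, an optional broad
Gaussian ridge (default 40 m high, 250 m across-crest SD), anisotropic
Gaussian mounds, and i.i.d. Gaussian elevation noise. The reference scene
plants 120 mounds on a jittered grid with heights U(6.5, 9) m, along-axis
SD U(4, 5.5) m, axis ratio U(0.6, 1) and random azimuth, giving delineated
widths of roughly 15–40 m. The flanks are deliberately steep
(height/SD ≳ 1.3): recovery is scored against the planted footprint (mound
term ≥ 0.2 m), and for flatter Gaussians that 0.2-m skirt spreads far
beyond any contour a threshold-based delineation can see — by construction,
not by deficiency — so low flat mounds would be scored unrecoverable no
matter the algorithm. Within the steep regime, delineation recovers
99–100% of planted mounds one-to-one with zero spurious detections at
noise SDs of 0 and 0.3 m; the occasional miss is a pair of adjacent mounds
delineated as one (flagged) outline.

Presence labels are Bernoulli draws from a logistic model over z-scored
attributes, default intercept 0.7 with coefficients +1.2 (MaxWD), +0.9
(Max_Rug), +0.7 (BPI), −0.4 (MaxCurrent): deeper, rougher, more prominent
mounds are more likely to carry live coral, with a mild penalty for the
fastest currents — the qualitative driver structure reported for the real
reef, at effect sizes that give a ~2/3 presence rate matching the observed
82/120. Z-scoring makes the coefficients scale-free. For present mounds a
coral-cover disc is placed on the up-current (default south-west) flank and
sized by bisection to a target cover fraction drawn U(0.05, 0.8).

What the scenes do *not* emulate: spatially correlated survey noise
(motion/navigation artefacts), real mound shapes (asymmetric, coalesced,
terraced), patchy multi-colony cover geometry, and any true hydrodynamic
coupling between terrain and the current raster. Passing recovery tests
therefore demonstrates the correctness of the chain's geometry and
statistics, not field-level detection rates.

## Numerical and degenerate-input choices

- Raster formats: ESRI ASCII (text, written at full float precision so
  round trips are bit-exact) and single-band GeoTIFF with
  ModelPixelScale/ModelTiepoint/GDAL_NODATA tags; non-square cells and
  missing georeferencing are hard errors.
- Empty or all-nodata BPI rasters delineate to an empty list (with a
  warning when all-nodata); an annulus larger than the grid yields an
  all-nodata result plus a warning.
- Features containing no cell centres get an all-NaN attribute record and
  a warning; a feature touching the raster edge cannot be infilled and
  raises.
- Diagonal-only cell adjacencies polygonise via a hairline (1e-6 cell)
  dilation so a region stays one polygon.
- Confusion-matrix rows with no samples yield NaN class errors, flagged
  rather than silently zeroed.
- Stratified splits that leave a class empty (possible with tiny classes)
  are re-drawn with a warning, up to 10 attempts.

## Problem sizes used in the checks

The acceptance script runs the 120-mound reference scene at full size
(700 × 1000 cells) for recovery, a 380 × 380 scene with 12 planted mounds
for attribute recovery, a 50 × 50 grid for the brute-force BPI
equivalence, and 200-sample tables for the model-sanity checks (20
permuted-label refits). These sizes give stable statistics while keeping a
full run around a minute.

## Known limitations

- Manual editing of merged outlines is out of scope; merges are flagged
  only, so attribute records of flagged features describe the merged
  geometry.
- `InitialSlp` on delineated (rather than skirt-covering) outlines carries
  the flank-residual bias described above.
- The five-class cover model is supported end-to-end but its evaluation
  reports only the confusion matrix and error rates (sensitivity/
  specificity/AUC are binary-only).
- GeoPackage/Shapefile output is not provided; the vector interchange
  format is GeoJSON.
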