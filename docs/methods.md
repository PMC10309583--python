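# Methods

This note records the models, conventions and numerical choices behind
`mitomorph`, in the order the pipeline runs.

## Imaging model and calibration

All quantification happens on 2D maximum z-projections of single channels;
the z axis exists in the data model (stacks are `(channel, z, y, x)`) but
only the projection is measured.  The default calibration is a 63×/1.4 NA
confocal acquisition with 2× zoom: 133.6 × 133.6 nm lateral pixels, 395.2 nm
optical steps, 8-bit intensities.  Lateral calibration is assumed isotropic;
areas are pixel counts × pixel area, polygon ROI areas use the shoelace
formula on the vertex path (the semantics of measuring a hand-drawn
selection), and masks rasterize polygons by the pixel-center-inside rule.

## Thresholding policy

One thresholding policy serves every binarization: Tsai's moment-preserving
threshold on the 256-bin gray-level histogram.  The preserved-moment system
gives two representative levels `z0 < z1` and a target fraction
`p0 = (z1 − m1)/(z1 − z0)` of pixels that should map to the lower level; the
threshold is the gray level whose cumulative histogram fraction is closest
to `p0` (first index on ties), and *foreground is strictly greater than* the
threshold — a deterministic convention for the off-by-one the definition
leaves open.  The mitochondrial (mitoDsRed-like) channel is thresholded on
its raw projection; only co-stain channels go through the enhancement chain
first.  Binary images are cleaned outside the relevant ROI after
thresholding.

## Enhancement chain

Four steps in fixed order, each disabled at its identity limit:

1. **Unsharp mask** (`radius` 2 px, `weight` 0.4):
   `(img − w·G_σ(img))/(1 − w)` with σ = radius; weight 0 disables.
2. **Rolling-ball background subtraction** (radius 50 px): implemented as
   subtraction of the grayscale ball-rolling background
   (`skimage.restoration.rolling_ball`); exactness versus any particular
   legacy implementation is not claimed.  `None` disables.
3. **CLAHE** (block 9 px, 256 bins, max slope 4): tile-based adaptive
   equalization; the clip limit is `max_slope / nbins`, so slope 1 clips the
   histogram to uniformity and is treated as disabled.
4. **Median filter** (radius 1 px, disk footprint); radius 0 disables.

Working range is 8-bit throughout; the output is clipped to [0, 255] between
steps.

## Per-mitochondrion morphometry

Mitochondria are 8-connected components of the cleaned binary mask with at
least `min_pixels` = 4 pixels (≈ 0.07 µm² at the default calibration, a
floor against shot-noise specks).  Touching rods count as one object — the
same ambiguity a manual scorer faces — and no watershed splitting is
attempted.

**Length** is the tip-to-tip extent of the organelle, the quantity a manual
segmented-line trace measures.  The estimator thins the component to a
skeleton, takes the largest geodesic distance between skeleton endpoints
(orthogonal steps = 1 pixel, diagonal = √2), and adds an end correction
equal to the component's mean width (area / geodesic length, floored at one
pixel, capped at the geodesic length).  Thinning retracts a rod's skeleton
by about half its width at each tip, so adding the mean width restores the
full extent; for a one-pixel-thin trace the correction reduces to the
classical one-pixel rule.  Components whose skeleton degenerates to a single
pixel get their equivalent circle diameter.  On rendered capsules at the
default noise level this estimator carries a mean absolute error near 10%
of the true length, with no systematic bias.

**Size classes** are half-open, lower-inclusive: fragmented [0, 1) µm,
elongated [1, 2), medium/large [2, 3), tubular [3, ∞) — so a 2.0 µm
mitochondrion is medium/large.

**Compartment metrics**: occupancy is 100 × mito area / ROI area; the arbor
additionally gets linear density (count / total dendritic length), linear
occupancy (100 × Σ lengths / total dendritic length) and area-per-length
(µm² of signal per µm of dendrite).  Soma and primary-dendrite ROIs are
always supplied, never inferred.

## Skeleton network metrics (soma)

The soma mask is skeletonized; skeleton pixels form an 8-connected graph
(with the redundant diagonal of every pixel triangle removed so paths follow
the thin skeleton), junction pixels adjacent within an 8-neighborhood are
contracted to single junction nodes, and endpoint-terminated spurs shorter
than 2 px are pruned as rasterization whiskers.  Branches are maximal paths
between nodes of degree ≠ 2; isolated cycles count as one branch.  Metrics:
footprint (mask area, by construction identical to the morphometry module's
mito area), mean branch length over all branches, mean summed branch length
and mean branch count over independent structures.  Single-pixel skeleton
structures contribute to the structure count but carry no measurable branch.
An empty mask returns zeros with a warning flag.

## Intensity quantification

Background is the mean of three 5 × 5 µm boxes drawn over signal-free
regions (box size enforced to ± 1 px).  CTCF uses pixel units consistently:
`CTCF = Σ intensities over the ROI − (ROI pixel count × background mean)`,
which keeps the formula dimensionally exact; negative values are flagged but
never clipped, preserving linearity for downstream statistics.  CTMF is
CTCF computed with the thresholded mitochondrial mask as the ROI, divided by
the mask area in µm² — the background-corrected numerator is used, so a
uniformly stained mask of any size gives the same CTMF.  Both the
mask-normalized CTMF and the soma-ROI CTCF are emitted per cell.

## Colocalization

Channel "presence" is defined by the shared thresholding policy upstream,
never inside the colocalization functions.  Overlap is the pixelwise AND of
the two masks, reported as area and as a percentage of the compartment ROI.
Manders' coefficients weight by intensity: M1 = Σ of channel A over B's mask
÷ Σ of A over A's own mask, and symmetrically for M2.  Costes
randomization and Pearson pixel correlation are out of scope.

## Dendritic distribution

Branch orders are centrifugal (not Strahler): the primary apical dendrite is
order I and the order increments at every bifurcation.  A branch owns the
segment connecting it to its parent bifurcation, so branch lengths partition
the total dendritic length exactly.  Each mitochondrion is represented by
its centroid, snapped to the nearest branch within 1 µm (configurable;
dendrites are ~1 µm wide, so a larger snap would capture soma signal);
farther centroids are flagged unassigned and reported.  The position score
is the arclength fraction of the centroid's projection along its branch
(0 = proximal).  Branch-order fractions are percentages over a restricted
interval, II–V by default, of the mitochondria assigned within it.  The
count-versus-length relation is an ordinary least-squares fit with Pearson's
correlation (Spearman available); a constant response is reported with
r = 0, p = 1 and a degenerate flag.

## Statistics

For each metric and pair of groups: normality per sample by Shapiro–Wilk
for n < 50 and D'Agostino–Pearson for n ≥ 50 (n = 50 goes to
D'Agostino–Pearson, n = 3 to Shapiro–Wilk — explicit closures of interval
gaps, recorded in the decision trace); if both samples pass (α = 0.05), an
F-test of variances routes to the pooled t-test or Welch's correction;
otherwise the two-tailed Mann–Whitney U.  The full decision trace is part of
the result object.  Cumulative length distributions use the two-sample
Kolmogorov–Smirnov test (asymptotic p).  Fold-change data across ≥ 3 groups
use Kruskal–Wallis followed by Dunn's post-hoc z-tests on tie-corrected mean
ranks with Bonferroni adjustment.  Significance stars follow 0.05 / 0.01 /
0.001.  Individual tests are delegated to `scipy.stats`; the routing logic
and the trace are this package's contract.  Dunn's test is implemented here
because no installed library provides it.

## Synthetic neurons

The generator is the package's measurement standard, so its design choices
matter:

- **Geometry** is 2D (the analysis projects anyway); z is used only at
  render time.  A circular soma (radius 5 µm) anchors a primary dendrite
  (order I, 20 µm by default) that bifurcates with per-order probabilities
  into branches of gamma-like lengths (normal around 18 µm, clipped), up to
  order V.  Branches are three-segment polylines with small heading jitter.
- **Dendritic mitochondria** are spherocylinders of fixed diameter
  (0.4 µm).  A mitochondrion's *length* is its tip-to-tip extent along the
  branch — the same convention the length estimator targets — and the
  rendered capsule's centerline is retracted half a width per tip so the
  drawn shape spans exactly that extent.  Lengths are sampled from a named
  distribution (default lognormal, median 1.3 µm, σ 0.45, giving roughly
  30% fragmented / 55% elongated) and floored at 0.5 µm: rods shorter than
  their own diameter degenerate to sub-resolution spheres that no imaging
  pipeline can count, so they are not part of the simulated population.
- **Placement** draws a per-branch count from Poisson(density × branch
  length) and samples each center uniformly from the *exact* free arclength
  remaining (a hard-core process with a 0.35 µm minimum tip gap), so rods
  are lost only at genuine saturation and the realized density tracks the
  parameter.  Rods also keep a clearance from the soma network and from
  rods on other branches (resampled on conflict), which makes
  connected-component counts exactly recoverable in the noise-free limit.
- **The soma network** is a random geometric graph: points sampled in the
  disc, each connected to its nearest predecessor, segments accumulated
  until a target area fill fraction (default 0.55) is reached on a 20 px/µm
  bookkeeping grid.  Only its area fraction and skeleton metrics are
  quantitative claims; the topology is qualitative.
- **Rendering** places all structure on the central optical section, blurs
  with a 3D Gaussian PSF (σ = 0.17 µm lateral, 0.5 µm axial), renormalizes
  so the in-focus peak keeps its nominal amplitude, then adds a flat
  background (10) with a shallow left-to-right gradient (± 1), Poisson shot
  noise (`photon_scale` = 5 counts per intensity unit; ∞ disables) and
  Gaussian read noise (σ = 1.5), and quantizes to the configured bit depth.
  The optional co-stain channel paints the mitochondrial mask at a uniform
  spec intensity; because the PSF attenuates the in-mask mean below that
  nominal value, the generator records the *rendered* expected in-mask
  intensity as the recovery truth.  The optional lysosome channel grows
  ~0.35 µm puncta seeded on mitochondrial pixels until a target
  overlap-area fraction is met, plus free cytoplasmic puncta kept clear of
  the mitochondria; the achieved fraction is recorded as truth.
- **Determinism**: `(spec, seed)` fixes the geometry, `(geometry, cfg)` the
  rendering; cohort per-cell seeds spawn from the master seed via
  `SeedSequence`, and a re-run writes byte-identical datasets.

What the generator does *not* emulate: 3D structure (everything lives on one
optical plane), photobleaching and flat-field inhomogeneity beyond the
linear gradient, spectral bleed-through, tissue autofluorescence, mitochondria
inside spines, and axons.  Passing recovery tests therefore demonstrates the
correctness of the measurement chain under a faithful but simplified imaging
model, not performance on real tissue.

## Problem sizes in the test suite and acceptance script

The suite exercises compact cells (order ≤ 3–4 arbors, 14 µm primary
dendrite, ~200–400 px images) so the full run stays interactive: 20 cells
for segmentation recovery, 13 order-IV cells (> 500 rods) for distribution
recovery, 50 full-size geometries for the regression, 1000 replicates for
the type-I calibration, and 15 + 15 / 6 + 6 cell cohorts for the end-to-end
effect and null checks.  `scripts/acceptance.py` uses 10 cells per group.
These sizes are the package's own validation design; all of them scale up by
changing a parameter.

## Known limitations

- The PSF halo biases area occupancy of *dense* structures upward (the soma
  network reads ~5–10 points above its geometric fill); sparse dendritic
  occupancy is accurate to ~0.5 points.  This mirrors real confocal data.
- Touching mitochondria merge into one object; counts under-estimate at
  high density exactly as manual counting does.
- The Moments threshold assumes a bimodal-ish 8-bit histogram; on
  near-constant images it raises instead of guessing.
- The statistics router treats each metric independently; no multiplicity
  correction is applied across metrics in the cohort report.
- Branch-order analysis requires a traced tree; the package never traces
  images.
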