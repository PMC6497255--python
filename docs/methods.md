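# Methods

## Overview

`retimorph` quantifies the morphology of the segmented retinal
microvasculature and its change with age.  The pipeline consumes binary
vessel maps (the output of an external segmenter; segmentation itself is
out of scope), computes 25 parameterized traits for each of three caliber
classes of every image, and feeds the resulting trait tables into
age-association statistics and age-cohort classification.  A synthetic
vascular-tree and cohort generator with full ground truth makes every
stage testable without access to clinical imaging cohorts.

## Vessel maps and the caliber split

Input rasters are binarized at `> 0`.  Raw fundus photographs can be
reduced to the 565×584 analysis size by exact area-weighted averaging
(each output pixel averages the source area it covers) followed by
re-binarization at 0.5 coverage; area averaging preserves thin vessels
that nearest-neighbour decimation would drop.  The linear downscale factor
is reported as `sqrt(source_area / target_area)` (≈ 5.5 for a 3872×2592
source).

Caliber is estimated per skeleton pixel as twice the Euclidean distance to
the nearest background pixel, and per branch as the arithmetic mean along
the branch.  On a constant-width stripe of width `w` this reads `w` (even
`w`) or `w + 1` (odd `w`) — within one pixel of truth, which is the
accuracy this discretization admits.  The dataset-wide *uber-mean* `Um` is
the unweighted mean of per-branch calibers pooled over all images of a run
(per-image pooling is available for small fixtures).  Branch-level
averaging (rather than pixel-level) was chosen so long trunk vessels do
not dominate `Um`; the choice is isolated in `compute_uber_mean`.

Each branch is assigned whole to a caliber class: *Thick* if its mean
caliber is at least `F·Um` and *Thin* otherwise, with `F = 0.5` by
default.  Ties score Thick, consistent with the observation that the bulk
of segmented vessels fall in the Thick class.  Class masks attribute every
foreground pixel to its nearest branch centerline, so Thin and Thick
partition the Total foreground exactly.  The *Total* class is the
untouched input mask.

## Skeleton analysis and branch tracing

Masks are thinned with a standard topology-preserving medial-axis
algorithm.  Every skeleton pixel is classified by its crossing number
(CN): half the number of binary transitions around its 8-neighbourhood in
cyclic order.  CN 1 marks a terminal, 2 a ridge, 3 a bifurcation, ≥ 4 a
crossing.  Adjacent same-type junction pixels (a thinning artifact at
thick forks) merge into one counted junction.  The junction traits are the
cluster counts: j1 terminals, j2 bifurcations, j3 crossings.

j3 is computed but excluded from default statistical panels: apparent
crossings in a 2-D projection are overwhelmingly overlaps of distinct
vessels rather than real junctions (a "phantom" trait), and carry no age
information.  A flag restores it.

Branches are maximal skeleton paths between junction/terminal pixels:
junction pixels are removed, each remaining 8-connected chain is ordered
by walking from a free end, and one adjacent junction pixel is re-attached
at each open end so branches stay anchored at their forks.  Chains without
free ends are cycles and are flagged closed.

## Tortuosity traits (t1–t15)

Seven base measures are computed per branch from arc length `L_c`, chord
length `L_x`, and the signed curvature `κ` of the arc-length-parametrized
contour (central finite differences,
`κ = (x′y″ − y′x″)/(x′² + y′²)^{3/2}`):

| base | definition |
|------|------------|
| T1 | `L_c / L_x` |
| T2 | `Σ |κ_i| Δs_i` (total curvature) |
| T3 | `Σ κ_i² Δs_i` (total squared curvature) |
| T4, T5 | T2/L_c, T3/L_c |
| T6, T7 | T2/L_x, T3/L_x |

Each base yields a *sampled* value (anchor points as traced) and a
*smoothed* value (least-squares cubic spline with interior knots every 10
samples, resampled at unit arc steps), giving `t(2k−1)`/`t(2k)` for
k = 1..7, plus `t15 = L_c(smoothed)/L_c(sampled)`.  Per-image values are
unweighted means over branches with at least 5 skeleton pixels; closed
branches contribute no chord-based values.  Missing values are NaN and are
excluded — never zero-filled — downstream.

**Anchor sampling.**  Sampled anchors are every 5th skeleton pixel (both
ends kept).  Using every pixel would inflate the polyline arc length of a
digitized straight line by up to ~8% (staircase geometry), which both
distorts t1 far above the values seen in real vessels and drowns curvature
in lattice jitter; 5-px spacing brings the arc/chord ratio of a straight
rendered vessel to within ~0.5% of 1 while leaving genuine curvature at
vessel scale (tens of pixels) intact.  Analytic (float-coordinate) curves
are unaffected: the tortuosity operators take point sequences as given.

## Fractal traits (f2–f8)

Plain grid box counting, anchored at the image origin with no grid-offset
averaging.  For scale index s ∈ {2..8} the box side is `2^s` pixels; with
`N_s` occupied boxes and resolution `r_s = ceil(max(H, W)/2^s)` boxes
along the longest side, `f_s = log N_s / log r_s`, undefined when
`r_s = 1`.  This definition reaches its analytic limits exactly: 1 for a
1-px line and 2 for a filled dyadic-size image.

## Synthetic vascular trees

The generator grows a branching random walk on the pixel grid.  Tips
advance in unit steps; the heading diffuses with standard deviation τ per
step (default 0.05 rad — chosen to give arc/chord ratios in the 1.0–1.3
range typical of retinal vessels).  Segment lengths between branch events
are geometric with per-step probability `p_bif` (default 0.02, i.e. mean
segment ≈ 56 px) plus a 6-px minimum that keeps consecutive junctions
resolvable.  At a branch event the tip splits into two children deflected
20–40° to each side; child widths follow the Murray-type cubed-sum rule
`w_p³ = w_c1³ + w_c2³` with a split fraction drawn from U(0.4, 0.6).  Tips
stop at the image border, below 1 px width, or at the step cap.
Centerlines are rendered as discs of radius `w/2`.

Two features keep the rendered topology faithful to the bookkept truth:

* **Escape runs.**  Children travel their first 12 steps without heading
  noise, so forks render as clean Y junctions instead of braids.
* **Collision steering.**  An occupancy grid tracks grown vessels; a tip
  about to run into one stops a caliber short with probability 0.85 and
  crosses otherwise.  Crossings are wanted in moderation — they are what
  produces the phantom trait j3 — but unchecked collisions braid the
  skeleton and multiply spurious bifurcations.

Ground truth describes the *rendered* tree: a spawned fork whose children
never draw (step cap, border) is not a visible junction and is not
counted; a fork with one drawn child is a pass-through.  Under this
accounting the tree identity `endpoints = bifurcations + 2·roots` holds
exactly, and skeleton-measured j2 on sparse trees tracks truth within
~10%.

On dense trees the skeleton systematically over-counts bifurcations
(residual crossings and fork artifacts) by a stable linear amount:
`measured_j2 ≈ 1.42·budget − 7.8` under default growth parameters (fit
once over budgets 25–85, 12 seeds each).  The cohort simulator inverts
this relationship, so its age anchors are expressed directly in *measured*
j2 units.

## Synthetic aging cohorts

Participants draw age ~ U(20.3, 88.4) years and sex ~ Bernoulli(0.5).
The expected measured bifurcation count follows the line through (20 y,
j2 = 74) and (88 y, j2 = 31) — the magnitude of decline reported for
aging retinal microvasculature — implemented as a per-participant
bifurcation budget (growth stops branching once it is spent) with SD 6
participant-level noise.  Budgeted growth keeps segment-length statistics
age-independent, so branch-level tortuosity is age-null by construction
(τ has zero age slope by default).  Eight cardiovascular/anthropometric
covariates (systolic/diastolic BP, waist, hip, weight, height, BMI,
carotid IMT) are generated at ordinary adult clinic magnitudes with fixed
age correlations (e.g. 0.45 for systolic BP, 0.50 for IMT); they correlate
with age but have no causal path to vessel morphology, which is what the
covariate-adjusted regression is meant to demonstrate.

Trait values in the cohort table are measured by running the actual
pipeline on every rendered map (skeletonization, crossing numbers, branch
tracing, box counting) — never copied from ground truth.  The default
measurement set (t1, t3, t5, j1, j2, j3, f3; Total class, sampled
tortuosity only) keeps a 300-participant cohort under a minute on one
CPU; `full_traits=True` computes all 25 traits per image through the
standard path.

**What the emulation does and does not show.**  Junction counts and their
age trend are controlled directly and recover cleanly (Pearson r ≈ −0.8
at n = 300, far stronger than the r ≈ −0.3 seen in real cohorts, where
biological and photographic variance dominate).  Two indirect couplings
are properties of the generator worth knowing: f3 declines with age
(sparser networks fill fewer boxes) without being programmed, and t5 —
total squared curvature, unnormalized — picks up a weak negative age
coupling through density (junction-anchored branch ends contribute
curvature kinks).  t1 and t3 are the reliable programmed-null controls.
Passing tests on these cohorts demonstrates the *pipeline's* recovery
properties, not that real retinas behave this way: the generator has no
optic disc geometry, no artery/vein distinction, no segmentation noise,
and uniform rather than cohort-structured ages.

## Statistics

Age association is Pearson correlation per trait with two-sided p-values,
adjusted by Benjamini–Hochberg step-up FDR within the scanned panel (the
FDR family is the trait set of one call; j3 excluded by default).
Association and regression reduce the table to one analysis row per
participant first (first image by id).  Young/old summaries split at a
given age (default: cohort median) and report subgroup means and
shared-bin histograms.

The covariate model is OLS of each trait on
`A + A² + A·S + S + x1 + … + x8` with intercept, sex coded {0,1} and the
interaction as a literal product.  Rank-deficient designs raise with the
names of the collinear columns.  Across a trait panel, p-values are
FDR-adjusted per model term.

## Classification

Participants are binned into age classes by configurable ranges.  Ten
randomized twofold splits assign *participants* (with all their images) to
train or test; per-class training pools are equalized by downsampling the
larger classes.  Per split, on training data only: features are
z-normalized, missing values imputed with training means, and selected by
three criteria — Fisher score (top 75) for the WND classifier, and mRMR
and CMIM (top 30 each) for two linear SVMs (C = 1).  Mutual information
uses 10 equal-frequency bins fitted on training data.  WND scores a test
sample against class c as the mean over training samples t of c of
`d(x,t)^-5`, with d the Fisher-weighted squared Euclidean distance; exact
duplicates short-circuit to their training class.  The WND exponent −5
follows the weighted-neighbour-distance literature.

Reported accuracy is the mean over (classifier, split, class) cells, each
cell being the fraction of that class's test images called correctly —
i.e. the average of per-class rates over the three classifiers and ten
splits, which equals the pooled correct-call frequency on balanced test
sets.  The no-information level is 1/K for K classes.  By default the
feature set is the microvascular trait columns; identifiers, age, sex,
the cardiovascular covariates and simulator ground-truth columns are
never used as features.

## Numerical and degenerate-input conventions

* Coordinates are 0-based (row, col); image sizes quoted width×height.
* Empty vessel maps are flagged, not errors; empty caliber classes yield
  all-NaN trait vectors; constant traits yield NaN correlations.
* Curvature at chain ends uses one-sided differences (numpy gradient).
* Spline smoothing falls back to a single least-squares cubic (and
  finally to the raw contour) when a branch is too short or degenerate.
* Growth headings are rounded to 1e-6 rad before stepping so rendered
  lattices are reproducible across platforms; every stochastic entry
  point requires an explicit seed.
* Fisher scores cap at 1e12 when the within-class variance is zero.

## Problem sizes used in the shipped checks

Desk-scale runs use full-size (565×584) images throughout.  The
parameter-recovery check uses 20 replicate cohorts of n = 300 (one image
per participant); classification calibration uses null cohorts of
n = 120–150 with all 25 traits measured and a planted-effect cohort of
n = 120; the box-counting and crossing-number oracles are exhaustive at
their natural sizes (all 256 neighbourhoods; every scale of a 512×512
mask).

## Known limitations

* Arteriole/venule discrimination, optic-disc geometry, and segmentation
  itself are out of scope; trait values on real images inherit whatever
  biases the upstream segmenter has.
* The caliber estimate is discretization-limited to ±1 px and reads high
  on odd widths; `Um` inherits this bias coherently, so the F·Um split is
  insensitive to it.
* Box counting uses a single origin-anchored grid; grid-offset averaging
  would reduce quantization noise at coarse scales but break the exact
  brute-force oracle equivalence.
* The skeleton over-counts junctions on dense vasculature; the simulator
  calibrates around the effect, but absolute junction counts on real
  images should be interpreted as skeleton-level, not anatomical, counts.
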