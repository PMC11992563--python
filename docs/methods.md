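# Methods

## Data model and units

A localization table has one row per blink: integer `blink_id` and `frame`,
coordinates `x_nm`/`y_nm`, a 0-based `channel`, and optional `intensity`.
All internal coordinates and radii are nanometres; densities are reported
per μm² (1 μm² = 10⁶ nm²). Coordinates are continuous positions with the
origin at the lower-left corner of a rectangular field; there is no pixel
grid. Fields are either `open` (a crop of a larger sample) or `toroidal`
(periodic). Synthetic fields default to toroidal so that spatial statistics
need no edge correction; analyses of real crops use a guard region instead.

The native CSV header is `blink_id,frame,x_nm,y_nm,channel,intensity`; a
ThunderSTORM-style dialect (`x [nm]` / `x [um]` columns, `id`, `frame`) is
read with unit normalization to nm. Only the coordinate columns are
mandatory on input; the rest are defaulted.

## Synthetic fields

The generator emulates an antibody-labeled membrane protein imaged by
STORM:

- **Placement.** Monomer mode places molecules by a homogeneous Poisson
  process at a given intensity (molecules/μm²). Clustered mode places
  nanodomain centers by a Poisson process and puts exactly
  `copies_per_cluster` molecules at each center plus isotropic Gaussian
  displacements of SD `domain_sigma`. A `fixed_count` switch replaces the
  Poisson number by its rounded expectation for exact-count tests.
- **Blinking.** Each molecule emits `blink_count` blinks drawn from a
  configurable family: `zero_truncated_poisson` (default — every labeled
  molecule appears at least once), `fixed`, or `geometric`, all
  parameterized by the mean (default 6.6 blinks per antibody, the value a
  single isolated antibody shows). Only the mean enters the downstream
  copy-number ratio, so the family is a sensitivity knob, not a claim about
  dye photophysics; on/off kinetics and frame correlations are not modeled.
- **Localization error.** Each blink lands at the true molecule position
  plus an isotropic Gaussian of SD `loc_sigma` (default 10 nm). Antibody
  linkage displacement (~10 nm) is not modeled separately; it is absorbed
  into `loc_sigma`.
- **Two colors.** `independent` draws both channels independently;
  `colocalized` places channel-1 molecules at channel-0 positions plus a
  Gaussian of SD `coupling_sigma`; `excluded` redraws channel-1 molecules
  until they clear a hard-core radius around every channel-0 molecule
  (with a feasibility guard of 10⁴ rejections per point).

Ground truth (molecule positions, domain membership, per-molecule blink
counts, blink→molecule map) is returned alongside the table, and the
generator is bit-reproducible given config + seed.

What passing tests on these fields do **not** show about real data: there
are no spurious background localizations, no drift, no frame-dependent
blinking, no multi-dye antibodies, and labeling efficiency is 100%. Copy
numbers are therefore relative to the single-antibody blink background
exactly as measured, with no labeling-efficiency correction.

## Two-stage segmentation

Stage 1 runs DBSCAN (textbook semantics: a core point has ≥ M₁ points,
itself included, within ε₁; clusters are maximal density-connected sets;
border points join the first core cluster that reaches them; labels are
renumbered by first occurrence in input order). Stage 2 computes each
coarse cluster's convex-hull area (degenerate clusters of ≤ 2 or collinear
points count as area 0 and are included in the average, which lowers it and
sends more clusters to refinement); clusters strictly above the mean area
(with a relative tie guard of 10⁻⁹ for floating-point hull areas) are
re-clustered by DBSCAN at `n_eps_steps` radii evenly spaced from ε₂ to ε₁
inclusive, M₁ unchanged. The maximum non-noise cluster count k over the
sweep (1 if every radius yields none) parameterizes an agglomerative
hierarchical re-segmentation (scipy linkage, Ward default, cut at exactly
k). Refinement is split-only: the final noise set equals the coarse noise
set, final labels never merge coarse clusters, and the final cluster count
is monotone. Distances are plain Euclidean even on toroidal synthetic
fields — clusters are local, and test fields keep a margin from the seam.

### Default parameters and their calibration

ε₁ = 30 nm, M₁ = 2, ε₂ = 16 nm, 8 sweep steps, Ward linkage.

These were calibrated once on ground-truthed synthetic fields at the two
regimes the method is used in — 72 monomers/μm² (mean nearest-neighbor
spacing ~59 nm) and 11 nanodomains/μm² of 7 molecules at 15 nm spread —
with the following reasoning:

- ε₁ just above the ~25 nm FWHM of a single-antibody blink cloud
  density-connects a whole cloud while minimizing bridges between
  neighboring molecules. Larger radii (e.g. 50 nm) percolate neighboring
  clouds into chains at 72/μm²; the above-average-area gate then misses
  most two-molecule merges because large chains inflate the mean area, and
  the recovered density drops by ~20%.
- M₁ = 2 labels only fully isolated blinks as noise. The synthetic model
  contains no spurious localizations, so stronger noise rejection would
  mostly discard real 1–2-blink molecules; for real data with false
  positives, raise M₁ (CLI-exposed).
- ε₂ = 1.6× the localization precision balances two failure modes: smaller
  values fragment the dense blink cloud of a genuine nanodomain (inflating
  cluster counts and deflating copy numbers), larger values cannot separate
  monomers merged at ~40–60 nm spacing.

With these defaults, recovery on 10×10 μm fields averaged over 5 seeds is
65.7 ± 0.9 clusters/μm² at a true 72/μm² (the residual ~9% undercount is
physical: molecule pairs closer than ~30–40 nm are unresolvable at a 10 nm
localization spread, and the blink-calibrated copies/μm² stays within a few
percent of truth because merged clusters carry proportionally more blinks),
11.6 ± 0.3 domains/μm² at a true 11.1/μm² with 6.6 copies per cluster at a
true 7, and the overlay FWHM reads ~23.5 nm at a true 25 nm (split
fragments at low density narrow the pooled displacement histogram
slightly). At very low densities the sweep occasionally finds spurious
sub-structure inside a single blink cloud, giving a ~5–8% oversplit; both
biases are visible in the test suite and are the documented operating
characteristics of the algorithm, not corrected post hoc.

Known limitation: the sweep's cluster-count criterion cannot distinguish "a
merged pair of molecules" from "density fluctuation inside one cloud" at
scales between ε₂ and the cloud diameter; any choice of ε₂ trades one error
for the other.

## Cluster metrics

Per cluster: blink count, centroid, per-axis pooled SD about the centroid,
hull area. Per field: cluster density (clusters per μm² of the analysis
region), mean blinks per cluster ± SEM (SD is also reported, since per-cell
"±" conventions vary), copies per cluster (mean blinks / background blinks,
with a nearest-integer report, half away from zero), copies/μm², molecules
per cell (× surface area, default 150 μm², reported to 2 significant
figures), and the attachment fraction (100 × final/initial density,
nearest-integer percent). The background blink count is an input — measured
from isolated antibodies or taken from the generator — never inferred from
the field itself.

The overlay analysis pools (blink − centroid) displacements over clusters
with at least `min_blinks` (default 3) blinks. Centroid centering shrinks
the per-axis variance of an n-blink cluster by (1 − 1/n); the
shrinkage-corrected overlay rescales each cluster's displacements by
√(n/(n−1)), and both raw and corrected spreads are available. The FWHM fit
bins one axis in 1 nm bins over ±5 SD and least-squares fits
a·exp(−(x−μ)²/2σ²); FWHM = 2√(2 ln 2)·σ ≈ 2.355σ. Note that a 25 nm FWHM
corresponds to σ ≈ 10.6 nm, while σ = 12 nm corresponds to a 28.3 nm FWHM —
both conventions appear in the literature for the same images; this package
exposes σ and FWHM separately and converts only by the closed form.

## Spatial statistics

All estimators operate on arbitrary point sets; the pipeline applies them
to final-cluster centroids by default (protein organization is a statement
about resolved clusters), with raw blinks as an option.

- NND: distance to the nearest other point, toroidal metric if the field is
  periodic. CSR reference: mean = 1/(2√λ).
- Pair correlation: g(r_k) = (ordered pair count in annulus k) /
  (n_centers · λ · annulus area), λ = n/area, so CSR → 1. Pairs at exactly
  zero distance are counted in the first bin.
- Ripley: K(r) = (1/(n_centers·λ)) Σᵢ #{j≠i : d ≤ r}, L(r) = √(K/π); CSR
  gives K = πr², L − r = 0. Radii beyond half the field (toroidal) or
  emptying the guard region raise an error rather than silently biasing.
- Voronoï: on toroidal fields the tessellation is computed on the 3×3
  periodic tiling and read off the central copy, so all cells are bounded
  and areas sum to the field area exactly; on open fields unbounded cells
  are excluded and flagged. Poisson-Voronoï reference: cell-area CV ≈ 0.53.

Edge modes: `toroidal` (exact for periodic fields), `guard` (points within
r_max of the border serve as neighbors but not centers), `none`. No
isotropic (Ripley-style weighted) correction is implemented.

## Two-color cross-correlation

The estimator histograms all inter-channel pairwise distances in `bin_width`
(default 25 nm) bins to `r_max` (default 1000 nm) and divides bin-wise by
the mean histogram of `n_random` (default 20) re-draws in which **both**
channels are replaced by uniform points of the observed counts — making the
estimator exchangeable in its arguments; the ensemble depends only on the
sorted channel counts, so cross_correlation(A,B) ≡ cross_correlation(B,A)
exactly. The per-bin envelope is the 2.5%/97.5% quantiles of the
randomized ratios using Weibull plotting positions — at n_random = 20 this
is the ensemble min/max, the classical Monte-Carlo envelope with two-sided
coverage 1 − 2/(n+1) ≈ 0.90, and measured CSR "random" verdict rates are
~93%. The first bin [0, 25 nm) operationalizes the zero-distance limit:
above/below/inside the envelope classifies
colocalized/excluded/random, except that a first bin expecting fewer than
10 random pairs returns `indeterminate`. The co-localization length is the
largest distance to which the curve stays continuously above the envelope
from r = 0. Points are raw localizations by default (cluster centroids
optional); ROI crops (e.g. 3×3 μm²) are first-class inputs.

## Pipeline and statistics

Per-field summaries are the unit of comparison between conditions; groups
are compared by an unpaired two-sample t-test (classic equal-variance form
by default, Welch as an option) with significance tiers at
0.05/0.01/0.001/0.0001. No cluster-count exclusion rules are applied; every
report carries n, the full parameter echo, a config hash (output paths
excluded) and the seed. Hierarchical-merge ties are resolved by scipy's
deterministic ordering, and all pipeline stages are deterministic given
config + seed.

## Problem sizes used in validation

The recovery experiments run 5 seeds of 10×10 μm fields (~47,000–52,000
blinks each); the overlay-FWHM experiment uses ~2,000 well-separated
clusters on a 32×32 μm field at 2 molecules/μm²; the cross-correlation
calibration averages 50 replicates of 3×3 μm two-channel fields at
50 points/μm² (the first distance bin expects only ~44 random pairs, so
single-replicate values scatter by ~15% and a large replicate count is
needed for a stable zero-distance estimate). These sizes give Monte-Carlo
errors comfortably below the effects being checked while keeping the whole
validation suite at desk scale.
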