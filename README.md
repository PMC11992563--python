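# stormclust

Cluster analysis and spatial statistics for single-molecule localization
microscopy (STORM/SMLM) point clouds, built for counting membrane-protein
copies on cell surfaces.

A STORM experiment reports one row per detected photoswitching event
("blink"), and a single dye-tagged antibody blinks several times, so blink
clusters are not protein clusters until the repeated blinking is calibrated
away. This package implements the full chain needed to go from a
localization table to protein-organization statements:

- **Two-stage density-based segmentation.** Coarse DBSCAN at radius
  ε₁ with neighborhood size M₁ removes stray localizations and forms
  preliminary clusters; every cluster whose convex-hull area exceeds the
  average over all clusters is then revisited: DBSCAN is re-run at a sweep
  of radii from ε₂ up to ε₁ (M₁ unchanged), the maximum number of
  sub-clusters k over the sweep is recorded, and if k > 1 the cluster is
  re-segmented by agglomerative hierarchical clustering (Ward linkage by
  default) cut at exactly k. Refinement only ever splits clusters; noise is
  decided once, by the coarse stage.
- **Copy-number bookkeeping.** With N̄ the mean blinks per cluster and N̄_bg
  the mean blinks of isolated single antibodies on the coverslip, copies per
  cluster = N̄ / N̄_bg; copies/μm² = cluster density × copies per cluster;
  molecules per cell = copies/μm² × cell surface area; the
  cytoskeleton-attachment fraction is the ratio of post- to pre-crosslinking
  cluster densities.
- **Overlay FWHM.** Blinks of every qualifying cluster are re-centered on
  the cluster centroid, pooled, histogrammed per axis and fit with a
  Gaussian; FWHM = 2√(2 ln 2)·σ.
- **Spatial-order statistics.** Nearest-neighbor distances, the pair
  correlation function g(r), Ripley's K(r) and L(r) − r, and Voronoï cell
  areas, with toroidal or guard-region edge handling, for contrasting
  random, lattice-like and clustered organization.
- **Two-color cross-correlation.** The inter-channel pairwise-distance
  histogram normalized by an ensemble of uniform re-draws of both channels;
  at vanishing distance the normalized value is < 1 / ≈ 1 / > 1 for
  excluded / independent / co-localized channel patterns, with a
  Monte-Carlo envelope for classification.
- **Synthetic field generator.** Ground-truthed localization fields —
  Poisson-placed monomers or multi-molecule nanodomains, configurable
  blink-count distributions (mean ≈ 6.6 blinks per antibody), isotropic
  Gaussian localization error, and two-color fields with independent,
  co-localized or excluded structure — used to validate every estimator
  against known truth.

## Worked example

Simulate a 5×5 μm field of monomeric membrane proteins at 72 molecules/μm²,
segment it, and summarize:

```sh
stormclust simulate --mode monomer --density 72 --width-um 5 --height-um 5 \
    --seed 1 --out locs.csv --truth-out truth.csv
# wrote 11819 blinks from 1801 molecules to locs.csv

stormclust cluster locs.csv --out clusters.csv
# 1306 coarse -> 1679 final clusters (51 noise blinks)

stormclust analyze locs.csv --cluster-table clusters.csv \
    --background-blinks 6.6 --out summary.json
# 1679 clusters, 67.2 clusters/um^2, mean blinks 7.0
```

The field truly contains 1801 molecules (72.0/μm²). The two-stage
segmentation resolves 1679 clusters (67.2/μm², a ~7% undercount from
molecules closer than the localization spread allows to separate), and the
summary reports `copies_per_cluster = 1.06` and
`copies_density = 71.3 /μm²`: merged molecules show up with proportionally
more blinks, so the blink-calibrated total stays at the true density — the
conservation that justifies copy-number counting. The overlay fit reports
`fwhm_x = 24.3 nm`, `fwhm_y = 23.9 nm`, the cluster size expected from a
10 nm localization error.

Other subcommands: `spatial` (NND/g(r)/Ripley/Voronoï curves), `xcorr`
(two-color classification with envelope), `compare` (unpaired t-test of a
per-field metric between conditions), `run` (end-to-end from a YAML
config). All parameters are echoed into every report together with a config
hash and seed; identical seeds reproduce identical outputs.

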