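# Methods

`ishscreen` implements an image-analysis screen for transcripts enriched in
the hippocampal neuropil, as seen in high-resolution colorimetric in situ
hybridization (ISH) sections. The method ranks genes by how much their
staining texture, in and around the hippocampal cell-body layers, resembles
that of canonical dendritically targeted transcripts. This note documents the
model, the defaults, the synthetic data the package is validated on, and the
numerical choices.

## Pipeline overview

1. **Localization.** A 15-point deformable shape model — 8 control points on
   the Ammon's-horn (AH) stratum pyramidale midline, 7 on the dentate-gyrus
   (DG) stratum granulosum — is fitted to a preprocessed section by
   Differential Evolution. A separate two-step affine registration
   (damped least squares, then Particle Swarm Optimization) matches a section
   against a small reference atlas to choose the slice level
   (levels 117–175, default 145) and the hippocampal ROI.
2. **Segmentation.** Three areas of interest (CA1 and CA3 curvature maxima,
   medial DG) are partitioned into 13 named regions — CA1a–d, CA3a–d, DGa–e —
   band core (`a`), lateral band flanks (`b`/`c`), and neuropil strips
   (`d`, plus `e` for the DG). A two-stage Random-Forest check accepts or
   rejects each segmentation; rejected slices trigger retries at neighbouring
   atlas levels and ultimately discard of the gene.
3. **Texture.** Each region is described at one or two window sizes by eleven
   features: seven first-order statistics and four Haralick features of a
   16-level, symmetric, non-directional gray-level co-occurrence matrix
   (GLCM), giving a 220-dimensional named descriptor
   (20 region–window pairs × 11 features).
4. **Selection and ranking.** On a 20-gene training set (3 positive
   prototypes, 17 negatives), near-duplicate features (|r| > 0.99) are
   removed; a binary GA with two-group silhouette fitness is run 15 times and
   features selected in ≥ 50 % of runs are kept. Candidate probes are ranked
   by Pearson correlation between their selected-feature vector and the
   prototype vector (the mean of the positives), after a pre-filter removing
   probes whose reported hippocampal expression level and density are both
   ≤ 20. The r ≥ 0.8 and r ≥ 0.7 cut lines are reported as columns, not
   enforced.

A small qPCR helper implements 2^−ΔCt relative quantification against an
Fmr1 reference and the synaptosome / total-brain enrichment ratio used to
validate candidates.

## Synthetic sections

Every stage is validated on generated sections with known ground truth
(`ishscreen.synthetic_data`). The generator emulates a parasagittal
hippocampus: two non-intersecting elliptic arcs carry the AH and DG cell-body
bands (8 px wide by default) on a light background (intensity 230, Gaussian
noise SD 6). Dark puncta are placed by a Poisson process — `soma_density`
(30 per 100 px²) inside the bands, `e · soma_density` in a neuropil margin
flanking each band on its stratum-radiatum side, where `e ≥ 0` is the planted
enrichment. Band puncta model packed somata (flat core radius 1.5 px,
Gaussian shoulder, amplitude 170), which renders the band near-confluent, as
in real sections. Neuropil puncta model fine transcript granules and are
smaller (0.5 px) and fainter (amplitude 70); this keeps the margin's
darkening graded over the whole `e ∈ [0, 2]` range used by the synthetic
screen instead of saturating early, matching the "granular, less intense"
appearance of genuine neuropil signal. The margin begins a 3.5 px guard gap
beyond the band edge so that at `e = 0` it is exactly clean background.

Puncta counts are drawn through the Poisson quantile function at a fixed
uniform deviate and positions from a per-region stream, so a fixed seed makes
the realization at lower `e` a strict subset of the one at higher `e`: margin
intensity is provably monotone in `e`, and all rasters are bit-identical
under a fixed seed.

What the generator does **not** model: counterstain and tissue background
texture, section artifacts (tears, bubbles, staining gradients), 3-D slice
geometry, other brain structures, and the optics of real ABA imagery.
Passing tests therefore demonstrate correctness of the algorithms and
recoverability of planted structure, not performance on real atlas images.

## Localization details

Preprocessing: optional median/IQR matching to pooled training statistics,
saturation of the darkest/brightest 1 %, CLAHE, then Otsu binarization
keeping the five largest dark connected components (ties broken by raster
order of the first pixel).

The fitting energy is the negative mean over polyline samples of
`inv + fg + (inv − inv_outside)`, where `inv` is Gaussian-smoothed (σ = 2)
inverted intensity, `fg` the Otsu-foreground density box-filtered at the
band width, and `inv_outside` the smoothed inverted intensity probed two band
widths away on the outer-normal side. The first two terms pull the polylines
onto dark, signal-dense tissue; smoothing makes the landscape descendable
despite punctate signal. The contrast term exists because a strongly enriched
neuropil margin (`e > 1`) can be darker than the band itself: the band is the
only dark ridge backed by light tissue on its outer side, so the contrast
term disambiguates the two ridges.

The search space is pose (translation ±25 px, rotation ±0.25 rad, isotropic
log-scale ±0.2 about the mean-shape centroid) plus principal-component mode
coefficients bounded at ±3 SD; modes are learned from 30 jittered template
geometries. DE uses target-to-best/1 mutation with F = 0.7, uniform
crossover at rate 0.9, population 64, 200 generations; the population is
evaluated as a batch (polyline resampling is a fixed linear operator on the
control points), which keeps a fit at ~0.4 s per section.

Registration similarity is the sum of squared differences on σ = 2 smoothed
images, with a phase-correlation translation initializer before the damped
least-squares affine refinement; the best candidates are polished by PSO
(24 particles, 40 iterations, c1 = c2 = 2.05, inertia 1.0 → 0.1). A
normalized correlation below 0.3 signals registration failure.

## Segmentation details

Area boxes are centered on the maximum-turn-angle control points of the CA1
and CA3 halves of the AH chain (endpoints, flagged, if the chain is
collinear) and on the arc-length midpoint of the medial DG half; box side is
twice the mean control-point spacing. Within each box the split is geometric
around the fitted midline: band regions occupy |d| ≤ 0.8·(band width / 2)
(the 0.8 inset buffers against localization error), `a` is the central half
along the band axis and `b`/`c` the lateral quarters; neuropil strips are one
band width wide starting one guard gap beyond the band edge, on the positive
normal side (both sides for the DG). The nominal band width comes from the
pipeline configuration rather than from the Otsu boundary: with a confluent
band and (for positives) a signal-dense margin, the Otsu mask does not
delimit the band reliably, but it is still required to be non-empty in every
area — an empty mask is the segmentation-failure signal. Pixels are assigned
in canonical region order, so the 13 masks are disjoint by construction.

QC stage 1 is a 100-tree Random Forest classifying pixels as inside/outside
the cell-body bands from intensity and local mean/SD/entropy in a 9×9
neighbourhood, trained on ground-truth labels of the synthetic cohort. Twelve
random points are sampled (uniformly over the mask) in each of CA1a, CA1d,
CA3a, CA3d, DGa, DGd and scored against the expectation that `a` points are
in-band and `d` points are not. QC stage 2 is a second forest mapping the
pooled point accuracy, the per-tested-region accuracies, and per-region
(area, mean, SD) statistics to accept/reject; it is trained on correct
segmentations (label accept) versus segmentations displaced by 2.5–4 band
widths (label reject). The per-region accuracies matter: for a strongly
enriched gene the neuropil points legitimately classify as signal-dense
tissue, so pooled accuracy alone cannot separate "correct segmentation of a
positive" from "misplaced model" — the band-core accuracies are
enrichment-invariant. Slice retry starts at level 145 and alternates
outward (−1, +1, −2, …); a gene whose every slice fails is discarded with a
logged reason.

## Texture details

GLCMs use 16 uniform levels (`v → ⌊v/16⌋`), the four unit-distance offsets
pooled with both orderings counted, then normalized. First-order features use
raw 8-bit intensities; histogram energy and entropy use the 16-bin normalized
histogram with 0·log 0 = 0. Degenerate-window conventions: coefficient of
variation, skewness, kurtosis and GLCM correlation are 0 for constant
windows, so every window yields finite features. Kurtosis is the plain
standardized fourth moment (3 for a Gaussian).

Windows tile the region's bounding box, anchored top-left, non-overlapping;
windows with ≥ 50 % of pixels in the mask are kept and their features
averaged. If none qualifies the single best-covered candidate is used; if no
candidate fits, one window is centered on the region centroid and flagged.
For thin band regions the window sizes (14–36 px) exceed the band width, so
the windows deliberately cover the band plus its immediate surroundings.

Window map (region: sizes): CA1a/CA3a/DGa/DGe 18 and 36; CA1b/c, CA3b/c,
DGb/c 24; CA1d/CA3d/DGd 14 and 28 — 20 pairs × 11 features = 220.

## Selection and ranking details

Silhouette distances are Euclidean over per-feature z-scores computed on the
training set; the features mix intensities, ratios and entropies on very
different scales, so some standardization is required for the index to be
meaningful (Pearson ranking is affine-invariant, so the same standardization
is harmless there and shares code). Degenerate cases: an element with zero
distance to both groups scores 0; an empty feature mask scores −1 so it can
never win. The GA uses one-point crossover (0.8), per-bit flips (0.06),
tournament selection of size 4, generational replacement with one elite, and
returns the best-ever mask of each run. Consensus keeps features selected in
≥ ⌈runs/2⌉ of the runs (8 of 15); an empty consensus falls back, flagged, to
the maximal-frequency features. Ranking ties are broken by probe id; probes
are treated independently even when they map to the same gene.

## Problem sizes and reproducibility

The default synthetic screen is 20 training genes (3 positive / 17 negative,
planted e in [1.2, 1.6] vs [0, 0.3]) plus 30 screen genes with e on an even
grid over [0, 2], at 192×256 px — sizes chosen so a full end-to-end run
completes in about a minute on one core while every stage still operates in
its intended regime. All stochastic stages (generator, DE, PSO, GA, forests,
QC sampling) draw their seeds from named children of one master
`SeedSequence`; two runs with the same configuration produce byte-identical
artifacts (`ranked.tsv`, `features.tsv`, `mask.tsv`).

## Known limitations

- The energy functional, the geometric sub-region split, the QC feature rows
  and the silhouette distance standardization are declared package defaults;
  they are reasonable but not uniquely determined by the published
  description of this class of pipelines.
- The screen is validated on synthetic sections only; headline corpus-scale
  statistics of the original ABA screen (discard rates, absolute Pearson
  values of specific genes, the identity of the selected feature subset)
  depend on the atlas imagery and are out of scope.
- The atlas-registration step is exercised against synthetic atlases; there
  is no bundled reference atlas.
- The silhouette criterion does not intrinsically prefer redundant
  informative features, so the consensus subset should be read as "sufficient
  separating set", not as the unique biologically meaningful set.
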