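# Methods

This note records the models implemented by `masp`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would want written down.

## Data model

A micro-scaffold experiment produces one sample per occupied micro-well.
`SpatialGrid` stores the lattice (rows × cols, µm per well edge) and a strict
bijection between specimen ids and (row, col) wells; coordinates are 0-based
with row 0 at the top, matching image raster convention.  `QuantMatrix` is a
samples × features table of log2 abundances with NaN for missing
measurements and a `scale_tag` that tracks the normalization chain
(`log2_raw → log2_tic → log2_ref → zscore`; z-scoring is reachable from any
stage).  Operations never reorder samples without carrying ids, so the
specimen↔well bijection survives the whole pipeline.  Matrix and map tables
are written as TSV/CSV with 6-significant-digit floats, `NA` for missing, and
`#` metadata headers; reading back reproduces exactly the decimal written.

## Normalization

**TIC centering.**  Each sample's log2 profile is shifted by
(sample mean − grand mean).  With missing cells, all means are taken over
observed cells only, and the grand mean is defined as the mean over *all*
observed cells (not the mean of per-sample means): under that definition the
grand mean is conserved exactly by the transformation even with unbalanced
missingness, and after centering every sample's mean equals it.  The
operation is idempotent.  It is applied to whatever feature level the input
carries — peptide-level before rollup in the original workflow, but
protein-level matrices transform identically.

**Reference normalization.**  Long acquisitions drift; pooled QC aliquots
injected periodically (here one per ~20 specimens) provide a moving
reference.  Each specimen is assigned the QC run nearest in acquisition
order (ties to the earlier run) and the QC run's log2 profile is subtracted —
equivalent to a ratio on the linear scale.  A protein missing from the
assigned QC run falls back to its median across all QC runs; a protein absent
from every QC run is left unchanged and logged.  The pipeline runner
TIC-centers before the reference step so both sides share a scale.  Whether
the reference step should be a log2 subtraction or something else is a
genuine design opening; the log2 subtraction was chosen because it is the
linear-scale ratio practitioners expect, and it is flagged in the API docs.

**Z-scores.**  Per protein across locations, sample standard deviation
(divisor n−1; the divisor is a convention choice, n−1 matches the CV
computation downstream).  Proteins with zero variance or fewer than two
observed cells get z = 0 at observed cells with a warning — a flat map is
more useful than a vanishing one.

## Maps and rendering

`build_map` is a pure re-indexing: the multiset of observed values in a map
equals the multiset of that protein's values over grid specimens.  Rendering
uses a fixed three-anchor green → yellow → red gradient (anchors hard-coded
for reproducibility; any matplotlib colormap name may be substituted), with
values clipped to the display range first — the default range for z-scale
maps is [−1, 1].  Color is monotone in value within the clip range.  Missing
wells render light gray; unoccupied wells are outside the map domain and stay
background white, so off-tissue positions are visually empty rather than
"missing".  No smoothing or interpolation is applied between wells: each well
is one uniform block (16×16 px by default).

Completeness is summarized as the fraction of proteins observed at every
occupied well ("complete maps") and the fraction observed at ≥95 % of wells;
grid specimens absent from the matrix count as missing wells.

## Map statistics

**Correlation.**  Pearson r (or cosine similarity) over pairwise-complete
wells; pairwise-complete handling was chosen because completeness is high and
imputation would manufacture spatial signal.  The two-sided p uses the exact
t transform t = r√(df/(1−r²)), df = n_pairs − 2.  Pearson needs ≥3 joint
wells, cosine ≥1.

**Bonferroni r-threshold.**  Inverting the same t transform at
α/n_tests gives the smallest significant |r|: r* = t_c/√(t_c²+df) with
t_c = t⁻¹(1 − α/(2·n_tests), df).  The exact t inversion is used rather than
a normal approximation.  At n_obs = 208 and n_tests = 5018 (a ~5019-protein
dataset correlated against one target) the threshold is 0.301 — the familiar
"r > 0.3 is significant" calibration at this scale.  n_tests defaults to the
number of comparisons actually made.

**Clustering.**  Affinity (1 + pairwise-complete Pearson r)/2 between
vectorized maps (so the grouping is invariant to per-map affine rescaling and
map order), spectral clustering on the precomputed affinity (k-means on the
embedding, fixed seed).  With `k='auto'`, k is the position of the largest
eigengap of the symmetric normalized Laplacian, searched over 2…10; k = 1 is
excluded from the automatic search because correlation affinities keep the
graph fully connected, but can be requested explicitly.  Map-pattern pairs
with no usable overlap get affinity 0 (no similarity evidence).

**Regional (non-random) pattern detection.**  The statistic is Moran's I
with binary rook (4-neighbour) adjacency over the occupied wells,
I = (n/S₀)·(zᵀWz)/(zᵀz).  This is this package's own choice of a standard,
transparent spatial-autocorrelation statistic for "does this protein have a
coherent regional pattern?"; the original GUI app cites an external approach
whose formulas are not public, so Moran's I serves as a documented stand-in.
Significance is by permutation: values are shuffled across that protein's
observed wells (B = 999 by default), p = (1 + #{I_perm ≥ I_obs})/(B + 1) —
the add-one form keeps p ∈ [1/(B+1), 1] and is exact under exchangeability.
Per-protein permutation streams come from `SeedSequence(seed).spawn`, so
results are reproducible and independent of protein order.  Benjamini–
Hochberg adjustment runs across proteins.  Proteins with <8 observed wells,
constant values, or no adjacent observed pairs are skipped with a warning
(8 wells is the smallest neighbourhood where a permutation null is
meaningfully sampled).

## QC and validation metrics

**Replicate CV.**  CV% = 100·sd/mean per protein on the linear scale
(2^log2), over QC runs with ≥2 observations; the median across proteins is
the headline number.  Linear-scale CV is the community convention for
abundance precision; log2-scale replicate agreement is reported separately as
pairwise Pearson r.  Multiplying a protein's linear abundances by any
constant leaves its CV unchanged.

**Cumulative linearity.**  R² of cumulative recovered amount against
specimen count 1…n (ordinary least squares).  Uniform recovery across the
slice gives R² ≈ 1; the metric is insensitive to permuting equal amounts.

**Spike-in accuracy.**  A designed pattern of non-endogenous peptides at
fold levels 0.5/0.7/1/1.3/2 is compared with its measurement on the linear
scale.  The measured map is first anchored so the 1-fold wells average to the
theoretical 1-fold level (the comparison is about relative pattern, not
absolute ionization efficiency), then mean |measured − theoretical|/
theoretical ×100 is reported per well and overall.  Anchoring makes the
metric invariant to a global multiplicative factor.  An `anchor='none'` mode
compares raw values for measurements already on the design's absolute scale.
Rank recovery (Spearman correlation of per-level mean measurement against
designed level) summarizes whether the fold ordering survives.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes, at
the scale of the experiment it was designed around:

| parameter | default | rationale |
|---|---|---|
| grid | 30×30 wells, 400 µm | the reference micro-scaffold geometry |
| occupied wells | 208 (elliptical mask) | a coronal-slice-sized tissue footprint |
| proteins | 2000 | desk-scale stand-in for a ~5000-protein dataset |
| regions | 4 contiguous angular sectors | coarse anatomical-region surrogates |
| regional proteins | 10 % of proteins, +1 log2 in one region | a clear but not trivial regional enrichment |
| noise | Gaussian, sd 0.3 log2 | multiplicative linear noise, the usual label-free error model |
| missing rate | 4.4 × 10⁻⁴ per cell, uniform | makes P(complete 208-well map) ≈ 0.912, the completeness regime of a good run; an intensity-dependent mode is available |
| QC runs | 9, interleaved ~1 per 20 specimens | the usual pooled-QC schedule |
| QC noise | multiplicative, sd 0.094 | ≈ 9.4 % replicate CV, a realistic label-free precision |
| heterodimers | pairs share s·latent + unit-scaled noise | two subunits of an obligate complex co-localize; correlation attenuates to s²/(s²+noise²) |
| spike noise | 10 % multiplicative | gives the folded-normal mean error 0.1·√(2/π) ≈ 8 % |

All randomness flows from one `numpy` Generator seeded by the truth's seed;
identical seed gives bit-identical output.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: per-run global loading/intensity drift (the
very thing TIC and reference normalization correct; those operations are
validated by their algebraic identities instead), peptide-to-protein rollup
and its shared-peptide ambiguities, intensity-dependent censoring as the
dominant missingness mechanism, spatial smoothness within regions beyond the
planted block offsets, and any LC-MS acquisition artifacts (carryover,
dynamic-exclusion stochasticity).  Headline numbers from real instruments —
median CV, spike error of an actual acquisition — are properties of the
instrument and sample, not of this code; the synthetic analogues check that
the *estimators* recover planted truth, not that the hardware performs.

## Problem sizes and runtime choices

The test suite and the acceptance script run the permutation machinery at
500 null proteins and 2000 preset proteins with B = 999 on 208 wells; the
permutation loop is vectorized (one B×n matrix product per protein), which
keeps the whole suite under half a minute on one core.  These sizes were
chosen as the package's standard desk-scale validation conditions.

## Known limitations

* Moran's I with rook adjacency is one reasonable regional-pattern statistic;
  patterns that are non-random but not spatially autocorrelated at lag 1
  (e.g. fine stripes) lose power.
* The Bonferroni threshold treats map comparisons as independent tests;
  spatial autocorrelation within maps inflates the effective sample size of
  each correlation and is not corrected beyond Bonferroni's conservatism.
* Reference normalization assumes the nearest-in-time QC run shares the
  specimen's drift state; no explicit run-order drift model is fitted.
* Cluster number selection by eigengap is a heuristic; for weakly separated
  patterns inspect `eigengap_scores` rather than trusting `k='auto'`.
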