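# Methods

This note documents the statistical procedures, their assumptions, the
defaults that matter, and the design decisions taken where the classical
literature leaves room.

## Data model

The analysis unit is the ecoregion. Floristic data are strictly
presence/absence: a boolean taxon × ecoregion incidence matrix whose taxa
carry a `range_flag` (`endemic` = range restricted to the hotspot,
`nonendemic` otherwise) and, for endemics, a `range_class` locating them in
one or both mountain systems. Taxa with no occurrence anywhere are tolerated
only in raw input and dropped (with a logged warning) before analysis;
hybrids and doubtful records are an upstream curation concern, handled only
through an optional `excluded` flag column. Identifiers are opaque strings.

All pairwise structures travel as a `DistanceMatrix`: labeled, symmetric
within 1e-12, zero-diagonal, non-negative. Every matrix is serializable as a
labeled square TSV, which is also the on-disk interchange format between
pipeline stages.

## Environmental variables

Twenty-two variables summarize each ecoregion: codes `1`–`18` are climatic
summaries of the ecoregion's monthly series (means, SDs, ranges, extreme
months, and extreme three-month "quarters" of temperature and precipitation)
and `E1`–`E4` are elevation summaries (mean, max, min, SD of cell
elevations). Conventions fixed here:

* monthly ecoregion series are **unweighted means over cells** — every cell
  covers the same 1 km², so area weighting is implicit;
* a **quarter** is any 3 consecutive calendar months with December→January
  wrap-around; ties between windows break toward the earliest start month;
  quarter precipitation codes (15/16) report the mean of the three monthly
  values, i.e. window total / 3;
* every SD uses the **n−1** denominator; a single-cell ecoregion reports an
  elevation SD of 0 rather than an error;
* extreme-month codes 13/14 take the extreme of the per-month ecoregion
  means (mean over cells first, extreme over months second). The opposite
  order (per-cell extremes, then averaged) is defensible; one order had to
  be fixed, and this one keeps all 18 climatic codes functions of the same
  12-value ecoregion series.

Lithology enters as relative surface fractions per substrate category (rows
sum to 1), normalized from a surface-area table.

## Dissimilarities

* **Sørensen**: `1 − 2a/(2a+b+c)` on assemblage pairs (shared `a`, unique
  `b`, `c`). No abundance weighting — the data are incidences.
* **Bray–Curtis** on lithological compositions.
* **Standardized Euclidean** on a variable subset: each variable is z-scored
  (n−1 SD) *over exactly the ecoregions in the current analysis*, so
  analyses on nested subsets standardize separately.
* **Geographic**: the mean planar Euclidean distance over all cross pairs of
  1-km² cell centers of two ecoregions. The full cell-pair distribution is
  summarized by its empirical mean directly (no density estimation); the
  median is available as an option, as is a seeded subsampling mode for very
  large grids whose Monte-Carlo error vanishes as the subsample grows. The
  matrix diagonal is defined as 0 and never used downstream.

## BIO-ENV

For every non-empty subset (size ≤ `max_k`) of candidate variables, the
standardized Euclidean matrix is built and the Spearman rank correlation
(average ranks for ties; Kendall optional) between the strictly-upper
triangles of the community and environmental matrices is computed. The
search is exhaustive — the classical procedure, not a stepwise variant — with
a 20-candidate guard; `max_k` defaults to the number of candidates. Ties
break toward the subset earliest in lexicographic enumeration order.
Climatic (codes 1–18) and altitudinal (E1–E4) candidate pools are searched
separately, and the winners feed separate predictor matrices.

## Clustering and support

UPGMA merges the cluster pair with minimal average inter-cluster distance;
node height is that distance, making the cophenetic structure ultrametric.
Ties break toward the lexicographically smallest pair of cluster
representatives (a cluster is represented by its smallest leaf label), so
the topology is fully deterministic.

Cluster support uses multiscale bootstrap. Taxon **rows** are the resampling
unit (they are the features describing each ecoregion). At each scale `r` in
0.5…1.4 (step 0.1 by default), `B` replicates draw `round(r·T)` taxa with
replacement; each replicate's Sørensen + UPGMA tree is scanned for the
reference clusters, giving per-scale recovery counts. Ecoregions emptied by
a draw are dropped from that replicate, and any reference cluster touching a
dropped leaf counts as unrecovered there. Counts are clipped to
`[0.5, B−0.5]`; `z_r = Φ⁻¹(1 − BP_r)` is fit by weighted least squares
(weights `B / (BP_r(1−BP_r))` on the probit scale) to
`z_r = v·√r + c/√r`, whence `AU = 1 − Φ(v − c)` and the fitted
`BP = 1 − Φ(v + c)`. Edges clipped at every scale carry no information for
the two-parameter fit and fall back to `AU = BP`, flagged; a single-scale run
degrades the same way with a logged warning. `B` defaults to 1000 per scale
(10,000 matches the heaviest published practice; tests run 100–200).

## Ordination

CA decomposes the χ²-standardized incidence table by SVD; site scores are
principal coordinates. DCA keeps CA axis 1 and re-derives axis 2 by
reciprocal averaging with **detrending by segments** (default 26): within
each equal-width bin of the axis-1 scores, axis-2 site scores are centered
to zero mean inside every iteration (tolerance 1e-10, ≤999 iterations).
Hill's nonlinear rescaling is deliberately omitted — axis lengths are not
interpreted here, only the site scatter. PCA runs on the correlation matrix
(the variables mix mm, °C and m); the largest-magnitude loading per axis is
made positive, a pure sign convention.

## MRM, partitioning, and permutation inference

Strictly-upper triangles are unfolded to vectors and fit by OLS. Pairwise
entries are not independent, so **no parametric p-value is ever reported**
for a matrix regression: significance comes from permuting the response
matrix's rows and columns by one common random relabeling, re-unfolding and
refitting (`nperm` defaults to 999; the observed statistic joins the null
count, the `+1/+1` rule). Coefficient tests are two-sided on `|b|`; the R²
test is one-sided. Exactly collinear predictor matrices are rejected by a
condition-number guard (1e8) rather than silently fit.

The semi-partial decomposition is leave-one-out: `unique_i = R²(full) −
R²(without i)`; `joint = R²(full) − Σ unique_i` absorbs all shared variance
in one term (it can be negative in suppression situations); `unexplained =
1 − R²(full)`. The three components sum to 1 by construction, and the
pipeline asserts this on every run. An all-subsets R² table (`commonality`)
is available when a finer decomposition is wanted. Unique contributions are
additionally reported as shares of their own total, since bar charts of
"variance explained by single factors" are conventionally rescaled that way.

The taxon-resampling robustness check draws `k` taxa with replacement,
rebuilds the Sørensen matrix and regresses it on the original matrix over
the shared ecoregions (ecoregions emptied by a draw are dropped for that
iteration; iterations with <3 survivors are discarded and counted),
reporting the mean and SD of the adjusted R² and the mean permutation
p-value. Adjusted R² follows `1 − (1−R²)(n−1)/(n−p−1)` with `n` the number
of ecoregion pairs; it may be negative.

A note on degenerate input: a pool in which every taxon has identical
incidence yields an all-zero Sørensen matrix, so the robustness regression
is undefined and raises a validation error rather than reporting a vacuous
perfect fit.

## Synthetic scenarios

The generator emulates the structure of a mountain-hotspot dataset, not any
real region: a rectangular grid of 1-km² cells partitioned into contiguous
block ecoregions with Dirichlet-jittered (hence unequal-area) boundaries; a
smooth multi-peak elevation field plus N(0, 40 m) noise; monthly temperature
as a seasonal cycle minus a 6.0 °C/km lapse, plus N(0, 0.4 °C) cell-month
microclimate noise; precipitation increasing westward with a summer minimum
and lognormal (σ=0.1) noise; and a nearest-seed-patch lithology mosaic. The
microclimate noise matters: without it, temperature is an exact affine
function of elevation and the climatic and altitudinal distance matrices are
perfectly collinear, which the MRM guard rightly rejects.

Floras: **nonendemics** occupy ecoregions with probability
`baseline × logistic(niche match) × exp(−decay·d)` where the niche match
compares the ecoregion's mean annual temperature to a species optimum
(breadth `climate_sd`, default 1.5 °C) and `d` is the centroid distance from
a seeded origin (decay 0.05/km by default); the origin is always occupied.
**Endemics** occur only where the ecoregion mean elevation falls within a
window (half-width `elevation_sd`, default 250 m) *and* a required lithology
category reaches an availability threshold, each such ecoregion occupied
with a fidelity probability; infeasible species are resampled a bounded
number of times, then dropped with a warning. Range classes are derived from
realized occurrences against the west/east metadata split. Defaults (12
ecoregions, 40×30 grid, 120 + 280 species) keep the full pipeline around a
second.

Two named scenarios pin the ground truth for recovery checks.
`distance_decay_scenario` (decay 0.12/km, broad 6 °C niches) makes geography
the dominant nonendemic driver. `lithology_endemic_scenario` (fidelity 1,
availability threshold 0.3, three categories in an 18-patch mosaic, 300
endemics) makes lithology the dominant endemic driver; the finer mosaic is
essential — with a handful of landscape-scale patches, lithological
composition varies smoothly with location and its unique contribution is
not separable from geography. The residual ambiguity in this scenario is
climate: because temperature is elevation-driven, the BIO-ENV-selected
climatic matrix can absorb part of the elevational niche signal, and on some
landscapes it edges out the altitudinal matrix. That is a property of the
confounded landscape, not of the estimator.

What passing these tests shows — and does not show. The generator plants
clean, separable drivers with modest noise; real floras add sampling
asymmetries, taxonomic inconsistency, spatially autocorrelated richness and
historically contingent ranges that no block-world generator reproduces.
Recovery here demonstrates that the estimators identify the dominant
planted gradient under realistic collinearity; it does not certify
effect-size accuracy on empirical data.

## Numerical choices and limitations

* Permutation p-value comparisons use a 1e-12 slack so ties with the
  observed statistic count as exceedances (conservative).
* BIO-ENV evaluates subset distances from precomputed per-variable squared
  distances; results are identical to rebuilding each matrix, just faster.
* The high-elevation ecoregion filter quantifies "a significant fraction of
  area above 1500 m" as ≥5% and "most of the surface below 500 m" as >50%;
  both thresholds are exposed parameters.
* UPGMA is O(n³) with a dictionary agenda — fine for tens of ecoregions, not
  for thousands of leaves.
* DCA reports two axes (the standard use here is a site scatter); eigenvalue
  2 is the contraction ratio of the detrended reciprocal-averaging iteration.
* Analyses assume planar km coordinates; there is no great-circle or CRS
  handling, and no GIS ingestion — rasters and shapefiles must be
  pre-tabulated to the cell/area tables the readers accept.
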