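# Methods

This note records the scientific and numerical choices behind `endemap`: what
each stage computes, the defaults and why, what the synthetic generator does
and does not emulate, and the known limitations.

## Geometry and distance

All coordinates are WGS84 decimal degrees. The study design targets equatorial
extents, where a lon/lat grid is nearly equal-area, so no projection is used;
every metric distance is great-circle (haversine, R = 6371.0 km). Analysis
grids (`GridSpec`) use half-open cells, `[west, east) × (south, north]`,
row-major from the north-west corner, so a record on a shared boundary falls
in exactly one cell. Raster surfaces (`RasterGeometry`, default pixel 0.1°)
are finer than the analysis grid and exported as ESRI ASCII text grids;
vector inputs and outputs are GeoJSON via shapely.

A record-poor cell inflates dissimilarity, so cells with fewer than 10
records are excluded (configurable) before any composition analysis.

## Range-size categories and the endemism surface (GIE)

Each taxon's range statistic is the haversine distance from the unweighted
centroid of its records to its farthest record. Eleven categories partition
[0, 2150] km with bounds 100, 200, 400, 600, 800, 1000, 1200, 1400, 1600,
2000 and 2150 km; larger ranges are clamped into the last category with a log
message (the category system was designed for a fauna without them).

Per non-empty category, a **quartic (biweight) kernel density**
K(d) = 3/(πh²)·(1 − (d/h)²)², d < h, is summed over the category's centroids.
The quartic kernel is the convention of desktop-GIS kernel-density tools; the
bandwidth defaults to the category's upper bound in km, tying the smoothing
radius to the range size the category encodes (both are configurable and
recorded in the run metadata). Each category surface is rescaled to [0, 1] by
its own maximum — which also makes the consensus invariant to rescaling any
category layer — and the consensus is their sum (`assembly="max"` optional).

### Area delineation

No canonical rule exists for cutting AoEs out of a continuous consensus, so
the rule is explicit, configurable and recorded in metadata. The default is
watershed-based:

1. background = the median of the consensus (the level set by widespread
   species);
2. candidate peaks = local maxima above background + 0.3·(max − background),
   at least 2° apart (merged below that);
3. basins = watershed of the negated consensus from those peaks, so
   neighbouring areas split at saddles;
4. each area = the connected pixels of its basin above
   background + 0.3·(peak − background).

A plain global threshold (`method="global"`: 8-connected components above
0.3·max) is retained; it is adequate for sharply peaked surfaces but merges
neighbouring areas across the widespread-species background on realistic
mixtures, which is why the watershed rule is the default.

### Synendemic species

An area's supporting species default to the **endemic rule**: range centroid
inside the area *and* range radius (max_dist_km) no larger than the area's
equivalent-circle radius. The second condition operationalises "endemic to":
a species whose range dwarfs the area cannot support it, and without the
condition any central area in a structureless dataset collects most
widespread species as spurious support. Pure `"centroid"` and
`"record"`-overlap rules are available.

## Sampling effort

Effort is the quartic kernel density of raw records (default bandwidth
200 km — about two grid cells, the scale at which collecting localities
aggregate; the value is a package choice, exposed as a parameter). Because
effort and endemism surfaces are both smooth, their pixel-wise correlation is
tested with **Dutilleul's modified t-test**: the autocovariance of each
surface is estimated on distance bins one pixel wide, and

  var(r) = tr(B·C₁·B·C₂) / (tr(B·C₁)·tr(B·C₂)),  M = 1 + 1/var(r)

(B the centering matrix) gives the effective sample size for a t-test with
M − 2 df. M is invariant to affine transforms of either surface. The
estimator is O(n²) in pixels; rasters beyond `max_pixels` (default 4000) are
regularly strided first, which preserves spatial structure and is
conservative. Calibration (in the test suite): on independent smoothed
Gaussian fields the corrected test rejects at 5–7% at α = 0.05 where the
naive test rejects ~80%; on white noise M ≈ n.

## Species-to-area fit

On the one-degree grid, fit = (a + b)/200 with a = % of the species' occupied
cells inside the area and b = % of the area's cells occupied. Species
distribution is the occupied-cell set, not an extrapolated range polygon. An
area's score averages its qualifying species (a > 90; the threshold is an
explicitly arbitrary restriction rule and is a parameter). Reports include
both averaging conventions — per-area means and the pooled mean over all
qualifying (species, area) pairs — plus the count of fully contained species
(a = 100) and the taxa qualifying nowhere.

## Composition pipeline

1. presence/absence matrix on the analysis grid (cells < 10 records dropped);
2. Bray–Curtis dissimilarity — on binary data this equals Sørensen,
   (b+c)/(2a+b+c); a record-count mode exists but binary is the default;
   beta diversity is additively partitioned into turnover
   min(b,c)/(a+min(b,c)) and nestedness (= total − turnover);
3. non-metric MDS (Kruskal stress-1, isotonic regression via scikit-learn
   SMACOF), k = 3 axes, best of `n_starts` random starts (default 100) plus
   one deterministic classical-scaling start, which also keeps stress
   monotone in k; reported: stress, non-metric R² = 1 − stress², and the
   linear R² of monotone-fitted disparities against ordination distances;
4. Moran's I per axis (queen adjacency between occupied cells,
   row-standardized; the weighting scheme is a package choice), two-sided
   permutation p with ≥ 999 permutations — the autocorrelation premise for
   interpolation;
5. ordinary kriging of each axis onto the raster: empirical semivariogram
   binned to half the maximum distance, exponential model fitted by weighted
   least squares (Cressie weights N(h)/γ²), linear-variogram fallback with a
   warning. With γ(0) = 0 on the system diagonal the predictor is exact at
   the data points; a kriging-variance surface is returned. This replaces the
   proprietary "empirical Bayesian kriging" of GIS suites — the method's only
   premise here is spatial autocorrelation, which step 4 checks;
6. RGB composite: each axis min-max scaled to [0, 255] into one channel
   (constant axes map to mid-gray with a warning).

## Barriers (Monmonier)

Cell centroids are triangulated (scipy Delaunay/Voronoi); each Delaunay edge
carries the dissimilarity of its two cells and is crossed by its dual Voronoi
segment (degenerate co-circular quads get a zero-length dual). A barrier
seeds at the uncrossed edge of maximal dissimilarity and extends from both
ends of its dual segment, always crossing the adjacent uncrossed edge of
greatest dissimilarity, stopping at the network boundary (infinite ridges,
clipped for display), at any existing barrier vertex, or on its own path.
Ties break toward the lexicographically lowest cell pair, making the
procedure fully deterministic; the original method's tie and stopping rules
are not published, so these are documented package choices. Default: top 15
barriers on the total Bray–Curtis matrix (turnover/nestedness selectable).

## Parsimony analysis of endemicity

Cells of a two-degree grid are terminals, species presences binary
characters, rooted on an all-absent hypothetical outgroup (standard PAE
practice). Invariant characters are pruned (logged); single-cell characters
are kept but flagged uninformative. Fitch state sets are bit-packed (two
bit-planes per node), so scoring costs a few big-integer operations per
internal node. The search is random-addition-sequence greedy starts followed
by SPR hill-climbing (SPR subsumes NNI) and a bounded plateau walk collecting
equally parsimonious topologies; this desk-scale strategy replaces the
large-matrix machinery of dedicated programs (sectorial searches, ratchet,
drifting, fusing) and is validated against exhaustive enumeration on small
instances (≥ 99/100 agreement on random 6-cell matrices). Outputs: all
distinct shortest trees, the strict consensus, and the clades supported by at
least one **non-homoplastic occurrence** — a species present in exactly the
clade's cells and requiring one step on every shortest tree. ("Unambiguous
support" could alternatively be read as Bremer-style support; the
synapomorphy reading is implemented.) Constrained searches force given cell
groups to be monophyletic (constraint-respecting starts, constraint-checked
SPR moves) and report the extra steps over the unconstrained optimum; a
shorter constrained tree, if ever found, lowers that optimum, so extra steps
are never negative.

## Classification and discriminant testing

The GIS-style unsupervised "maximum likelihood" classifier is a Gaussian
mixture with full covariances fitted by EM on per-pixel axis vectors, k-means
initialised, one model per group count in 2–11, reported with BIC; EM is
stepped an iteration at a time so the log-likelihood trace is recorded and
its monotonicity asserted. Candidate region schemes are tested by linear
discriminant analysis of axis scores at 100 random pixels per region
(without replacement), reporting the confusion matrix, per-region and overall
resubstitution hit percentages, and leave-one-out cross-validated hits; the
validation convention of the original GIS workflow is unstated, so both are
reported. Note that leave-one-out sits *below* chance when regions are truly
identical (the usual LOO anti-learning artifact at chance level).

## Synthetic worlds

`endemap.synthetic` generates occurrences with known truth: endemic species
drawn from isotropic Gaussians seeded inside planted polygons (σ log-uniform
between 0.3° and the polygon radius) and clipped to them; widespread species
over the whole extent (σ log-uniform between 3° and half the extent);
records per species Poisson with mean 90 (the records-per-taxon density of
the compilation it emulates); per-(species, river) Bernoulli crossing
decisions, with non-crossers redrawn on the seed side of the river (crossing
parity of the segment from the range seed); optional thinning proportional
to a relative effort surface. One global random stream is consumed in a
fixed, documented order, so runs are byte-reproducible by seed.

Presets: `three_aoes` (three disjoint 6°×6° interfluve-scale polygons, 20
endemics each, 100 widespread, seed 42), `one_river` (meridional river at
60°W, crossing probability 0.1, 150 widespread species, seed 11), `null`
(150 widespread species, no structure, seed 1), all on a 20°×20° equatorial
extent.

What the generator does *not* emulate: environmental gradients, phylogenetic
structure, abundance, anisotropic or disjunct ranges, coastline/elevation
constraints, or the taxonomic error structure of real compilations. A green
recovery test therefore establishes that the algorithms recover planted
geometric structure at realistic sampling densities — not that they would
settle empirical controversies about any real fauna.

## Numerical details and degenerate inputs

- Kernel surfaces evaluate only within the compact support window of each
  point (linear in points).
- A flat-zero consensus yields no areas; constant surfaces are rejected by
  the correlation routines ("constant surface"); constant kriging data give
  a constant surface; a constant RGB band maps to 128 with a warning.
- Bray–Curtis on two empty cells cannot occur (cells with zero presences are
  rejected upstream).
- Moran's I uses row-standardized weights and E[I] = −1/(n−1); a rook-weight
  checkerboard attains I = −1 exactly.
- Mixture covariances carry a small ridge (reg_covar 1e-6) against
  degeneracy.
- All stochastic routines take explicit seeds and are reproducible.

## Limitations

- The Dutilleul correction assumes second-order stationarity; strong trends
  inflate the long-distance covariance bins.
- Watershed delineation depends on the background estimate (median); a
  surface whose "background" is not representative (e.g., half the extent
  empty) may need an explicit threshold.
- The desk-scale PAE search is not meant for matrices with many hundreds of
  cells; it trades the specialised search heuristics of dedicated parsimony
  software for auditability.
- Barrier paths depend on the Voronoi geometry near the hull boundary;
  infinite ridges are clipped for display at an inflated bounding box.
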