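# Methods

This note documents the models, estimators, parameter choices and known
limitations behind rseikit, in the order the pipeline runs them.

## Grid model and I/O

All stages operate on pre-aligned, north-up, square-cell rasters in a
projected CRS. The toolkit deliberately contains no resampling or
reprojection: alignment is a precondition checked exactly (shape,
origin, cell size, CRS tag), and any mismatch is a hard error. This
keeps the numerics deterministic and the scope on the index mathematics;
co-registration belongs to upstream GIS tooling. Cells are equal-area,
so areas are `count x cell_size^2` (reported in km^2 for 500 m cells).

GeoTIFF I/O is implemented on the tifffile library, writing single-band
float32 with the standard GeoTIFF georeference tags (ModelPixelScale,
ModelTiepoint) and the GDAL nodata tag. Masked cells round-trip through
the nodata sentinel. Nodata propagates through every computation: any
arithmetic with a masked operand yields a masked cell, and masked cells
are excluded from every statistic (minima, maxima, covariances,
correlations, class areas).

## Water masking and component indicators

Open water has extreme spectral values in the moisture and dryness
bands; left in place it stretches the per-image min-max normalization
and lets the first principal component encode a water/land contrast
instead of the land-quality gradient. Water is therefore detected first
with MNDWI = (green - SWIR1)/(green + SWIR1) and a configurable
threshold (default 0.0, the standard convention), and water cells are
masked in every indicator layer.

Reflectance values outside [-0.01, 1.6] are treated as nodata before
any index math; scaled-reflectance products occasionally carry
out-of-range artifacts and a single bad cell would otherwise distort
the normalization extremes.

The five indicators are plain band arithmetic with division guards
(non-positive denominators mask the cell):

- SAVI with soil constant L = 0.5 by default (L = 0 reduces to NDVI).
- SWCI from the two SWIR bands.
- NDBBI: the published formula typesets ambiguously; the toolkit
  follows the original index definition, numerator
  `1.5*SWIR1 - (NIR + green)/2` with the matching denominator. The
  literal alternative reading (`1.5*b6 - b2 + b4/2`) is available via
  `grouping="literal"` so both conventions can be compared.
- LST = 0.02*DN - 273.15 Celsius (linear DN scaling; both the scale
  and offset are arguments).
- CSI: each of SI-T, NDSI, SI4 is min-max normalized over the land
  cells of the epoch being processed, then averaged cell-wise, so CSI
  is in [0, 1] by construction. Normalizing the sub-indices per image
  matches the normalization applied to every other indicator.

Each indicator layer is then min-max rescaled to [0, 1] over land.
Whether LST is converted to Celsius before or after this rescaling is
irrelevant — any affine transform of a layer yields the identical
normalized layer.

## PCA composition and orientation

The composite index is the first principal component of the 5x5
covariance matrix of the normalized indicators over land cells, with
each epoch fitted independently. Covariance (not correlation) PCA is
the standard choice once all inputs share the [0, 1] scale; the
correlation variant is available behind `use_correlation=True`.
Eigenvalues and unit-norm loadings come from a symmetric
eigendecomposition; contribution rates are eigenvalue shares of the
trace.

Eigenvector sign is arbitrary in any solver, so a conditional
"subtract PC1 from 1" step is replaced by a deterministic orientation
rule: if the PC1 score correlates negatively with SAVI, the score is
negated. After the subsequent min-max rescale the two conventions are
identical, and the rule guarantees the index increases with greenness
in every epoch. The `oriented` flag records when the flip occurred.

The rescaled index is graded into five classes at 0.2/0.4/0.6/0.8 with
lower-inclusive boundaries and 1.0 included in the top class.

## Temporal dynamics

Change-vector analysis operates on the ordinal class codes, not on raw
index differences: the change grade is the integer difference of codes
(-4..4), binned into five types ([-4,-2] deteriorated significantly,
-1 deteriorated, 0 unchanged, 1 improved, [2,4] improved
significantly). FROM-TO transition tables cross-tabulate class
membership over jointly valid cells; their marginals equal the
per-epoch class histograms, which the tests assert as a conservation
law.

The coefficient of variation defaults to population standard deviation
over mean per cell — the universal CV definition and the convention in
this literature. A mean-absolute-deviation variant
(`estimator="mad"`) is provided because one printed form of the
statistic reads that way; both are scale-invariant. Levels use the
fixed breakpoints 0.10/0.20/0.30/0.40, with everything above 0.40 in
level 5. Cells with non-positive mean are masked.

The Hurst exponent uses classical rescaled-range analysis. For every
window length tau from 2 to n/2 the series is partitioned into
non-overlapping segments; per segment R is the range of cumulative
mean-adjusted sums and S the population standard deviation; R/S is
averaged over segments with S > 0; H is the least-squares slope of
log(mean R/S) on log(tau). Segments with zero variance are skipped and
cells with fewer than 3 valid (tau, R/S) points are masked. Estimates
are clipped to (0, 1]: values outside are small-sample artifacts. At
archive-like series lengths (n = 12, tau in {2..6}) the estimator is
noisy and biased upward — the classical R/S statistic overestimates
0.5 on short independent series — so the persistence classes
(0.35/0.50/0.65 boundaries) should be read as qualitative at n = 12.

## Optimal-parameter geographical detector

The q-statistic is computed in its sum-of-squares form
q = 1 - SSW/SST, which with population variances is exactly the
N_h*sigma_h^2 weighted form and makes q exactly partition-additive;
single-sample strata contribute zero to SSW. q is invariant under
affine transforms of the response.

Discretization methods for continuous drivers:

- equal interval: breaks at min + i*(max-min)/k;
- quantile: type-7 empirical quantiles at i/k, duplicates merged;
- natural breaks: exact Fisher-Jenks dynamic programming minimizing
  within-class SSW over contiguous value-ordered classes (O(k n^2));
  above 10,000 points a seeded deterministic subsample of 10,000
  supplies the breaks, which then label the full vector;
- geometric interval: breaks at min + (max-min)(g^i - 1)/(g^k - 1)
  with multiplier g = 2 by default — a deterministic,
  monotone-in-class-index parameterization chosen because the method
  is conventionally named but rarely specified;
- standard deviation: interior breaks at mean + 0.5*sd*(i - k/2),
  clamped to the data range — likewise a documented parameterization
  of a method usually named without a formula.

Bins are half-open with the top bin closed; duplicate breaks are
merged and the realized class count reported. The optimal-parameter
scan evaluates every (method, k) pair for k in 5..10 by default and
keeps the maximum q; ties go to the smaller k, then to the method
order above. The full scan is attached for diagnostics.

Significance uses a seeded permutation test — the response is permuted
with strata fixed, p = (1 + #{q_perm >= q_obs})/(1 + B) — rather than
a noncentral-F approximation: it is assumption-free and exactly
reproducible. Interaction detection forms the cartesian product of two
label vectors (empty cells drop out); the product partition refines
both marginals, so q_ij >= max(q_i, q_j) up to floating point, and the
category rules (weaken/enhance/independent) compare q_ij against the
marginals and their sum with the boundary q_ij = max(q_i, q_j)
classified as bi-factor enhance. Sampling uses every spacing-th cell
in both axes, emulating a coarser regular analysis grid; rows with
missing values are dropped listwise per (response, factor) pair.

## Synthetic scenes

The generator emulates the statistical structure the pipeline needs to
see, not radiative transfer. A smooth latent quality field E in [0, 1]
(min-max-scaled Gaussian noise at a configurable correlation length,
default 8 cells) drives all bands linearly: NIR increases with E; red,
green and both SWIR bands decrease; thermal DN encodes
LST = 20(1 - E) + 18 Celsius. This reproduces the sign structure a
real arid-land scene shows (greenness/humidity load opposite to
dryness/heat/salinity) and makes the composite index a monotone
function of E at low noise. Per-band Gaussian noise (default sd 0.01
reflectance) is clipped with the reflectances to [0.01, 0.95]. Water
bodies are contiguous disk-grown blobs (default 5% of cells) with
green/SWIR1 overrides that make MNDWI strongly positive — exercising
the masking path realistically, unlike salt-and-pepper noise. Epoch t
of a time series uses clip(E + t*trend), so a negative trend produces
monotone degradation; the default 12 biennial epochs mirror a
2001-2023 biennial record. All randomness flows from one seeded NumPy
PCG64 generator; identical specs give bit-identical scenes.

Driver rasters are built by stratifying E into k quantile bins and
attaching a validation response y = mu_stratum + Normal(0, sigma) with
sigma^2 = Var_between*(1 - q0)/q0, so the population q of y given the
strata equals the target q0 exactly; sample estimates recover q0
within a few hundredths at n = 10,000. A continuous proxy (bin
midpoints plus within-bin jitter) is available for exercising the
discretization scan.

What the generator does not emulate: spatial autocorrelation of the
noise, cloud and snow contamination, sensor drift, mixed pixels,
anisotropic terrain effects, and seasonal phenology. Passing tests on
synthetic scenes therefore demonstrate algorithmic correctness — the
estimators recover known constructions — not radiometric validity on
real imagery.

## Problem sizes and defaults

Default study conditions: 128x128 cells at 500 m (a ~64 km square),
12 biennial epochs, water fraction 0.05, reflectance noise sd 0.01;
degradation experiments use trend = -0.03 per epoch and noise sd
0.005. Attribution samples every 2nd cell (~4,000 points) and uses
199 permutations in pipeline runs. These sizes keep a full pipeline
run around a second while leaving every estimator comfortably inside
its asymptotic regime except the Hurst map, whose n = 12 limitation
is inherent to the record length, not the implementation.

## Known limitations

- Alignment is checked with exact float equality; inputs produced by
  different GIS chains may need coordinate rounding upstream.
- The per-epoch min-max rescaling makes the index relative within each
  epoch; absolute cross-epoch comparability relies on each epoch
  spanning a comparable quality range (the classified-change machinery
  operates on grades for this reason).
- Fisher-Jenks above 10,000 points uses a deterministic subsample; the
  breaks are near-optimal but not guaranteed optimal for the full
  vector.
- The permutation test treats samples as exchangeable; spatial
  autocorrelation inflates significance for smooth fields, so p-values
  on gridded samples should be read with that caveat.
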