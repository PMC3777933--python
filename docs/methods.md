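# Methods

This note documents the models, the synthetic study conditions, and the
numerical choices behind `gomtuna`, in the order the pipeline runs them.

## Study domain and calendar

The domain is the box 39-45° N, 71-65° W, discretized as a 500×500 node grid
(nodes include the bounds; cell size ≈ 0.012° per axis). Coordinates are
decimal degrees, west negative, throughout. The fishing season is June 1 -
October 31; "two-week intervals" are calendar half-months (1st-15th and
16th-month-end), ten per season. This semimonthly convention — rather than
rolling 14-day windows — is the only reading under which a decade yields
exactly 100 periods and period labels such as "June 1-15", "July 16-31" and
"August 16-30" arise naturally.

`day_of_year` is 1-based days since January 1; the June-October restriction
is applied as a filter, not a re-origin. An affine shift of the time origin
would change only the model intercept, so nothing downstream depends on the
choice.

## Synthetic study conditions

The generator is not a convenience fixture: its defaults define the
conditions under which the pipeline is exercised and validated.

| parameter | default | rationale |
|---|---|---|
| years | 1996-2005 | the decade with prey data at usable resolution |
| hotspots | (42.2, -70.4, 0.25°), (43.5, -69.3, 0.30°), (41.5, -68.4, 0.35°) | western Gulf of Maine, eastern Maine coast, Georges Bank — the herring fishery's persistent grounds |
| drift_rate | 0.1° lon/yr east | matches the documented ≈2.5° eastward shift over ~27 yr |
| n_herring_per_period | 30 | ≈8,500 positions over a 12-yr fishery scaled to June-October half-months |
| tonnage | lognormal(3.0, 1.0) mt | purse-seine/trawl sets of tens of tonnes, right-skewed |
| n_schools_per_period | 3 | ≈670 schools over 27 seasons |
| school_mean / dispersion | 69 fish / NB k=1.5 | ≈46,000 fish in ≈670 schools; heavy-tailed school sizes (variance = μ + μ²/k ≫ μ) |
| attraction / jitter | 0.9 / 0.15° | schools predominantly track prey concentrations, the effect the association test must detect |
| survey index | a=3600, b=50 /° lon, σ=20 | positive link to hotspot longitude with r² ≈ 0.35 at the decade's longitude variance, the order of the reported field correlations |

School sizes use a negative binomial (Poisson in the k → ∞ limit) because
the count model's quasi-Poisson refit presupposes overdispersion the
generator must be able to produce; sizes are resampled until ≥ 3 fish
("more than two"). Positions are truncated to the domain and off-mask by
rejection sampling capped at 10⁶ draws — exact and simple. Each generator
operation draws from an RNG stream seeded by (seed, operation name), so
adding an operation never shifts another's draws, and equal seeds give
byte-identical output files.

The land/bathymetry mask is a deterministic synthetic coastline: cells
north-west of a polyline from (-71°, 41.8°) to (-68°, 45°) are excluded
(≈13% of the grid). It reproduces the *role* of the real filter — keeping
random null points out of land/estuary areas — not Gulf of Maine geometry.

What the generator does **not** emulate: fleet search effort and its spatial
bias, environmental covariates (SST fronts), realistic coastline/bathymetry,
within-season prey movement beyond the fixed hotspots, and autocorrelation
between periods. Passing tests therefore demonstrate that the estimators and
tests behave correctly under the assumed data structure, not that the
original field conclusions are reproduced.

## School-count model

Full model: log-link Poisson regression of fish per school on year, day of
year, latitude, longitude and all six pairwise interactions. The printed
sources are ambiguous between five and six interactions; six is exactly the
number of pairwise products of four main effects, so the default includes
all six, configurable via `GlmSpec`.

Fitting is IRLS on a column-standardized design (mean 0, sd 1; interactions
formed from raw covariates before standardization), tolerance 1e-8 on the
relative deviance change, at most 100 iterations; coefficients and standard
errors are mapped back to the original scale exactly (a per-column affine
transform). Overdispersion is declared when residual deviance / residual df
> 1.5 (strict); quasi-Poisson inference then uses φ = Pearson χ²/df, SEs
scaled by √φ, and two-sided p-values from the t distribution with residual
df — the conventions of R's `summary.glm` for `quasipoisson`. Point
estimates are identical to the Poisson fit by construction, and the
implementation is cross-checked against statsmodels' GLM to 1e-6 in tests.

Backward selection: at each round, among removable terms with p > α
(interactions first; a main effect becomes removable only when no retained
interaction contains it), remove the one with the largest p and refit. Ties
in p are broken toward the later term in the canonical ordering, for
determinism. Year and day of year are continuous covariates: the
interactions of interest express smooth spatial drift, and factor-coding
year would consume ~10 df per interaction at decade scale. Each term has 1
df, so the coefficient t-test equals the marginal F-test.

## Prey density surfaces

Weighted KDE with an axis-aligned bivariate normal kernel, evaluated on the
500×500 grid and renormalized to unit probability mass (truncation at the
domain boundary, no edge correction; the error is second-order for interior
hotspots). Per-axis bandwidths come from the quartile normal-reference rule
`b = 4·1.06·min(sd, IQR/1.34)·n^(-1/5)` computed on that period's
*unweighted* coordinates (the rule is weight-unaware); quantiles use linear
interpolation at position 1+(n-1)p and sd the n-1 estimator. **The kernel
standard deviation is b/4** — the convention of the estimator family this
rule was designed for; other KDE conventions treat the bandwidth as σ
directly and differ by a factor of four.

Kernel weights are the catch tonnage (schools: fish count), normalized
within each surface; only relative weights matter, so per-period vs global
normalization is immaterial and per-period is used.

A period needs at least 10 records to support a surface (configurable; the
sources are silent), otherwise it is skipped with a recorded reason — a
value, not an error, as is a period with zero coordinate spread.

The α utilization region accumulates cells in decreasing density order until
cumulative mass ≥ α, ties broken by row-major index. This makes the region
the smallest highest-density set: dropping its least-dense member falls
below α, and regions are nested in α by the greedy-prefix property.

## Association test

Distances are great-circle km on the IUGG mean-radius sphere
(R = 6371.0088 km) by the haversine formula; ellipsoidal geodesics differ by
< 0.5% at this scale. Distance to a region is zero for a point whose cell is
a member, else the minimum over member-node coordinates. For speed the
minimum is taken over the region's boundary nodes (members with a
non-member 4-neighbour); a test asserts equality with the full member-set
minimum. At the 500×500 resolution the node-vs-polygon discrepancy is
bounded by one cell diagonal, < 1.7 km.

Random points: exactly 2 per observed school per period, uniform over
unmasked water by rejection (capped at 10⁶ draws), from a per-period
substream of the run seed — so a period's draws are reproducible in
isolation. Periods without a usable surface or without observed schools are
skipped with reasons.

The pooled model `distance = a + c·1[random]` is the default (the procedure
is described as a single linear model); per-period fixed effects are
available behind a flag. The group proportions are identical in every
period, so period effects are orthogonal to the group contrast and the
pooled estimate is unconfounded. Significance is two-sided with a
directional conclusion ("observed closer" iff ĉ > 0 and p < α), avoiding an
unstated one-sided test. Also reported: the number of evaluated periods with
at least one observed school inside the 95% region, and the raw count of
such schools — both descriptive, neither a reproduction target.

## Centroid trend

Yearly centroids weight positions by fish count; the variability shown with
them is the **unweighted** sample variance of school coordinates (the
weighted form is not specified anywhere; a frequency-weighted variant is
available behind a flag). Correlation with the survey index uses centroid
*longitude* by default — the documented shift is longitudinal — with
latitude available for completeness; Pearson r with the t-based two-sided
p-value on n-2 df, requiring ≥ 3 common years and non-constant series.

For the survey generator, the closed form
r² = b²·Var(lon) / (b²·Var(lon) + σ²) (Var over the realized yearly mean
hotspot longitudes) predicts the index-position correlation; the trend
validation uses σ = 5 and 10 schools/period, for which that formula gives
r² ≈ 0.90 and hence detection power well above 90% at n = 10 years — a
design-time power calculation, not a tuned threshold.

## Problem sizes in the test suite

Validation runs use sizes chosen to make Monte-Carlo bands tight while the
full suite stays quick: GLM recovery and selection at n = 2000 with 100
seeds; association calibration as 200 null decades and 25 high-attraction
decades on a 100×100 grid (the spatial structure is resolved at ~0.06°,
coarse relative to nothing in the test's logic — only distances to a smooth
region are needed); KDE oracle comparisons on 50×50 grids with ≤ 200 points;
region properties on 100 random surfaces. The acceptance script runs the
full default analysis at 500×500.

## Known limitations

- The association null treats points as independent within and across
  periods; shared regions induce within-period correlation. The balanced 2:1
  design keeps the test calibrated in simulation, but a clustered-error or
  per-period variant would be more conservative with few periods.
- No effort offset exists in the count model (no effort data are defined),
  so "landings varied by X" statements are about reported schools, not
  standardized CPUE.
- Planar cell areas (degree²) are used for probability mass on the grid;
  at 39-45° N the cos-latitude variation across the domain slightly
  over-weights northern cells relative to true area. Contours and
  highest-density sets are affected only marginally and consistently across
  groups.
- The synthetic coastline is a straight polyline; tests of mask behaviour do
  not validate performance on convoluted real coastlines.
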