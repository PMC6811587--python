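# Methods

## The flow-hierarchy pipeline

The object of study is a directed, weighted network whose nodes are spatial
cells (planar km coordinates) and whose edge weights are trip counts.
Intra-cell flows are excluded everywhere: the statistic measures organisation
of movement *between* places, and a self-loop carries no information about
it. Geographic inputs must be projected to a planar frame before entering
the package; no spherical geometry is implemented.

**Hotspot levels.** The empirical Lorenz curve of cell outflows is piecewise
linear, so its derivative at (1, 1) is the slope of the final segment,
`s = n·F_max/ΣF`. The tangent there meets the x-axis at `x* = 1 − 1/s`, and
hotspots are the cells in sorted positions `k/n > x*` — algebraically the
top `ceil(ΣF/F_max)` cells. Selected cells are removed and the construction
repeats on the remainder, producing levels 1…L. Three termination rules
apply: a flat distribution (slope within 1e−9 of 1, where the tangent
construction degenerates), exhaustion of positive-outflow cells, or fewer
than `min_cells` cells remaining (default 1, i.e. iterate to exhaustion —
large cities genuinely support deep hierarchies, so no arbitrary truncation
is imposed). Whatever remains, including zero-outflow cells, becomes the
final level L; this choice (rather than discarding quiet cells) keeps the
level map a partition of the city, and is flagged in the assignment
metadata. Ties at the threshold are resolved deterministically: cells
strictly above the boundary value first, then boundary-valued cells in
stable input order.

**Φ and its nulls.** Φ is the tri-diagonal trace of the level-flow matrix T
(entries normalised to sum to 1; validation tolerance 1e−8, suited to long
floating-point pipelines). For L = 1 the band is the whole matrix and Φ = 1
by definition — degenerate, but well defined. The uniform null is the exact
closed form (3L − 2)/L². The rewired null is the outer product of T's
marginals over the grand total; it is implemented in the general
(unnormalised) form so it applies to raw count matrices, and it preserves
row and column sums exactly by construction. Empirically reported city
values of Φ fall in roughly 0.77–0.95; those derive from proprietary trip
data and are context, not a target this package reproduces.

## Trip-distribution models

All three models are production-constrained: per-origin out-totals `O_i` are
inputs and the models only allocate them across destinations, which mirrors
how Φ is estimated when out-flows are observed but the full OD matrix is
not. Masses default to cell populations and fall back to observed out-trips
when populations are absent.

* **Gravity:** `T_ij ∝ O_i · m_j^β f(d_ij)` with `f` either `exp(−d/λ)` or
  `d^−γ`. β = 1 is the classic linear form; β = 2 doubles down on
  destination mass.
* **Radiation:** `T_ij ∝ m_i m_j / ((m_i + s_ij)(m_i + m_j + s_ij))` where
  `s_ij` is the mass strictly inside the origin-centered circle of radius
  `d_ij`, excluding both endpoints (ties at exactly `d_ij` excluded). The
  finite-domain correction is applied as per-origin renormalisation rather
  than a `1/(1 − m_i/M)` factor — equivalent once the production constraint
  is imposed.
* **Population-weighted opportunities:** destination weight
  `m_j (1/S_ji − 1/M)` with `S_ji` the mass inside the *destination*-centered
  circle of radius `d_ji`. The circle convention is strict (cells at exactly
  the origin's distance excluded, so the origin itself is excluded and the
  destination included); the literature is ambiguous here, so an
  inclusive-ties variant is exposed as `pwo_inclusive_ties`.

Distances are Euclidean. Distinct cells at (near-)zero separation are
floored to 1e−9 km with a warning rather than rejected.

## The synthetic-city generator

The generator exists so that every pipeline stage is testable without any
external data. It emulates a gridded city (1 km cells) with: a right-skewed
distribution of cell activity, one or more activity centers, and
distance-decaying flows. Two ingredients are deliberately separated:

1. **The activity distribution** is a fixed multiset of population values —
   the radial profile of a compact reference city around the grid midpoint
   (Gaussian core of scale `kernel_width` by default; exponential Clark-law
   profile for sharp sub-center landscapes) plus a uniform floor
   (`floor_fraction`, default 2% of the peak). This multiset does not depend
   on where the centers are.
2. **The spatial arrangement** comes from ranking cells by a multi-center
   attractiveness field — centers drawn uniformly in a disc of radius
   `center_spread`, with geometrically decaying (Zipf-like) weights
   (`center_weight_decay`, default 0.9) — and assigning population values by
   rank. At `center_spread = 0` this assignment is the identity and the city
   is the classic monocentric onion.

The separation matters: naively scattering additive kernels changes the
Lorenz curve of outflows, which changes the number of levels L and moves Φ
for purely distributional reasons, swamping (and in practice inverting) the
spatial signal the dial is meant to control. With rank-matching, L is
invariant under the spread dial and the compact-to-scattered contrast
isolates spatial correlation, which is the property the generator is for.

Out-trips are proportional to population (`trips_per_capita`, default 1 —
Φ is invariant to this scale). Flows come from the configured trip model
(default: gravity, exponential deterrence λ = 5 km on the 20 km default
grid) with mean-preserving multiplicative log-normal noise of coefficient of
variation `noise_cv` (default 0.3; log-normal keeps flows positive, and the
mean-preserving parameterisation `σ² = ln(1 + cv²)`, `μ = −σ²/2` leaves
expected flows equal to the noiseless model). The noise model is pure test
scaffolding — real trip data's sampling process is not being imitated.

Two stock configurations:

* the **default monocentric city** (20×20 km, single Gaussian core of scale
  3 km): six levels, Φ ≈ 0.83 against a rewired null of ≈ 0.81, with the
  top four levels holding ≈ 98% of outflow;
* `polycentric_config()` (20 sub-centers, exponential 1 km kernels, λ = 2 km
  trips): the base for compact-vs-scattered experiments, where individual
  business-district-scale hotspots either stack into one core or fragment
  across the city. Compact cities score ≈ 0.92 versus ≈ 0.84 at a scatter
  radius of half the grid.

Sub-seeds for replicate ensembles derive from `numpy.random.SeedSequence`
branches of the master seed, so every ensemble is reproducible end to end.

### What the generator does and does not establish

Passing the generator-based tests shows that the pipeline recovers known
orderings from controlled spatial structure: Φ above the rewired null under
spatially correlated hotspot placement, Φ decreasing as centers scatter, and
the gravity estimate rising with the destination-mass exponent in a
plateau-cored city (where linear gravity spreads top-origin flow across
mid-levels and stronger mass dependence pulls it back into the top-level
band). It does not establish calibration against real cities: real trip
networks have thousands of cells, deeper hierarchies (L beyond 10), street-
network and land-use constraints, and measurement processes none of which
are modelled. In particular, at desk-scale grids (≈ 400–900 cells) the level
count L can flip by ±1 under coarse-graining, which quantises Φ by
~0.01–0.02; the scale-stability test therefore asserts a strong (ρ ≥ 0.6)
rather than near-perfect rank correlation across cell sizes, a limitation
that vanishes at realistic network sizes.

## Indicator statistics

Three explained variances per indicator: squared Pearson (linear), squared
Spearman (monotone), and LOESS `R²_L = 1 − RSS/TSS` from a locally linear
tricube-weighted fit of the indicator on Φ (span 0.75 by default, zero
robustness iterations so the variance decomposition refers to the plain
fit; both are exposed in the API and echoed in output). `R²_L` can be
negative for pathological fits; reports clip it at 0 but the raw value is
kept in JSON. Significance stars follow p < 0.05/0.01/0.001 on the Pearson
regression p-value; a seeded permutation option covers small samples.
Complete-case analysis per indicator, with the dropped count reported.

The multivariate stage fits three intercept-included OLS models (Φ only,
covariates only, covariates + Φ); the gain `R²_full − R²_cov` is
non-negative by nesting. Rank-deficient designs are rejected with the
offending columns named. Fits are unweighted; a population-weighted variant
is a deliberate non-feature until a use case demands it.

## Numerical conventions

* Coarse-graining bins are half-open `[k·s, (k+1)·s)` anchored at the
  origin; boundary cells go to the higher bin. Newly intra-bin flows are
  excluded, consistent with the global diagonal exclusion.
* The Loubar position count uses `floor(n·x* + 1e−9)` so that exact-integer
  tangent intercepts (common with integer trip counts) resolve to the strict
  reading `k/n > x*` instead of drifting on float error.
* Φ is clipped at 1 from above to absorb summation dust on band-only
  matrices.
* CSV round-trips write `repr(float)` and read with pandas'
  `float_precision="round_trip"`, giving bit-exact read(write(n)) identity.
* Duplicate OD rows are summed (weekly-aggregated sources repeat pairs);
  self-loop rows are dropped and counted in metadata.
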