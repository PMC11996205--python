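# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `fractaldim`.

## Input model

A trajectory is an ordered array of planar points with a constant sampling
interval `dt` (default 1/30 s, matching 30 fps video); point *i* is the
position at time *i·dt*, and no explicit time column is stored. All
estimators require at least two points and finite coordinates. Paths are
normalized before estimation (below), so raw coordinates may be in pixels
or millimetres.

## Box-counting conventions

Boxes are half-open, `[mε, (m+1)ε) × [kε, (k+1)ε)` after translating by
the grid origin and rotating by the grid angle θ. Indices come from floor
division, which rounds toward −∞, so negative coordinates index correctly
and origin sweeps never corrupt counts. A point exactly on a gridline
belongs to the upper/right box; to keep that convention stable under
floating point, a coordinate within a relative tolerance of 1e−9 of a
gridline is snapped to it before flooring. This matters for curves such as
the Koch curve whose vertices are exact multiples of the box side.

The exact counter enumerates, per segment, every crossing with a vertical
or horizontal gridline (crossing ordinates are built from exact gridline
multiples to minimize drift), sorts the crossings along the segment,
removes corner duplicates (tolerance 1e−9·ε per coordinate), and inserts
the box of each midpoint between consecutive crossings. Sorting is by the
segment parameter *t*, which coincides with lexicographic (x, then y)
ordering for monotone segments but remains well defined when x is constant
or decreasing. Every original vertex box is inserted as well: a vertex
lying exactly on a box corner is missed by the midpoint rule alone, and a
zero-length segment (repeated frame) contributes only its vertex box. A
segment lying exactly along a gridline is assigned to the upper/right row
of boxes, consistent with the half-open convention. One consequence worth
stating: a unit segment on an aligned grid of side 1/k occupies k+1 boxes
(indices 0..k), because the far endpoint sits on gridline k — the point
counter already counts that box, and the exact counter must dominate the
point counter.

The exact counter is validated against an independent brute-force oracle
(segment–rectangle clipping over every candidate box) and against
high-order oversampling (S = 10⁴), which converges to it on paths in
general position.

Logarithms are base 10 throughout; slopes, and therefore dimensions, are
base-invariant.

## Temporal sampling

`U(δ)` averages distances between points δ frames apart over the
⌊(n−o)/δ⌋ non-overlapping steps starting at frame offset *o* (1-based,
o = 1 by default; offsets are exposed because the estimate's dependence on
the starting frame is itself a quantity of interest). Under the scaling
law U ∼ Cδ^α, the dimension is D_T = 1 + (1 − α)·min(d, 1/α) with d = 2
for planar paths, reducing to 1/α for α > ½. When noise pushes a fitted α
to 1 or above, D_T is clipped to 1 and the estimate is flagged rather than
allowed to dip below the topological dimension of a curve. The default lag
set is δ = 1..100.

On exactly self-similar curves sampled at their construction vertices
(the Koch curve), U(δ) follows the scaling law exactly on dyadic lags but
oscillates around it at intermediate lags; a full-range OLS over δ = 1..100
then overestimates D_T (1.31 on the level-6 curve), while dyadic lags
{2^k} recover log 4 / log 3 to four digits. This is why the benchmark
script and the scale-selection machinery use geometric (dyadic) lag/scale
ladders; the same ladders guarantee monotone box counts under aligned
coarsening (λ² small boxes tile one large box).

The Takens correlation-sum estimator is included as an optional
cross-check, flagged experimental. It is consistent only as the pairwise
distance cutoff shrinks: on a uniform 1-D lattice the maximum-likelihood
form returns ≈ 2/3 when the cutoff equals the full extent (the pair
distance taper biases it) and ≈ 1 at a cutoff of a tenth of the extent.

## Normalization

Extent mode translates the bounding-box corner to the origin and divides
by η = max(x-extent, y-extent); mean-step mode divides by the average
consecutive-frame distance (proportional to average speed). Rescaling
shifts log N(ε) curves without changing slopes, so dimensions are
unaffected; its purpose is to align the informative scale band across
animals of different sizes and speeds. The unnormalized elbow η·ε\* scales
linearly with path speed, which is the mechanism that makes per-path scale
selection necessary in the first place.

## Scale selection

The dense initial set is S0 = {10^(−0.025k) : k = 0..400}. Refinement
defaults to the threshold rule (Method 1) with γ = 0.01 — scales with
γ·Nmax ≤ N ≤ (1−γ)·Nmax, largest consecutive run kept (ties favor the run
containing the largest scales). The regression rule (Method 2) fits
log₁₀ N against −log₁₀ ε over the span from scale 1 down to the largest
scale attaining Nmax (the bound "1" is read as scale value 1, where S0
starts) and keeps the largest run of scales strictly above the fitted
line; "strictly above" carries a 1e−9 tolerance so an exactly linear curve
yields an empty run instead of selecting float noise.

The elbow search runs on the original-counting curve — its smooth
saturation makes the elbow stable, whereas the exact counter's small-scale
fluctuations can let noise dominate the split error — and the resulting
ε\* is transferred to the other estimators through the multiplier ξ = 3
(configurable). Dual TLS computes, for every split i ∈ {2..K−2} of the
retained scales, the total squared perpendicular error of two orthogonal
line fits on (−log₁₀ ε, log₁₀ N). Internally the per-split SSE is the
smallest eigenvalue of the 2×2 scatter matrix, evaluated for all prefixes
and suffixes from cumulative moments in O(K); the module-level `tls_fit`
uses SVD, and the two are cross-checked against a brute-force angle-scan
in the tests. Ties (splits within 1e−9 relative SSE of the minimum) break
to the smallest i, keeping the coarse-scale branch short and
deterministic.

Final fits: box methods over {3ε\*, 4.5ε\*, 6ε\*}; temporal over
δ\*..2δ\* with δ\* = inf{δ : U(δ) ≥ 3ε\*}. A `coarse` preset (ε from 4ε\*
up to 10^−1.5 in 0.025 log-steps; δ\*..60) exposes the larger-scale
variant. γ, ξ, the S0 density and the preset are all configuration fields.

## Perturbation analyses

Origin sweeps shift the grid origin over a 20×20 lattice of [0, ε)²
(half-open, matching grid periodicity); rotation sweeps use 200 uniform
angles in [0, π); both report std/mean. Sweep dimension values use the
two-scale formula D(ε) = log₂(N(ε)/N(2ε)) at a shared origin. The global
minimum of N over origins uses nested lattice search (the 20×20 sweep
refined once inside the best cell) because N is piecewise-constant in the
origin with many local minima, defeating gradient methods. Temporal-phase
sweeps evaluate U(δ, o) over all offsets, and D_T over every combination
of per-lag offsets on lags δ..2δ — (2δ)!/(δ−1)! combinations, guarded
above 10⁵ — with the per-(lag, offset) U values precomputed once and the
per-combination slopes evaluated as a vectorized weighted sum.

## Synthetic data

The generators define the validation conditions:

- **Koch curve** — exact construction-order vertices, base (0,0)–(1,0),
  bumps on the positive-y side (the orientation is fixed here so box
  counts are reproducible). Known dimension log 4 / log 3.
- **Brownian motion** — Gaussian increments of standard deviation σ√dt
  per coordinate; displacement exponent ½, graph dimension 2.
- **Correlated random walk (larva-like)** — lognormal step lengths
  (mean speed 1 unit/s, CV 0.3) and wrapped-normal heading increments with
  standard deviation 1/√κ, κ = 10 by default; 30 fps. Lognormal/wrapped-
  normal were chosen for positive support and simplicity. Higher κ gives
  straighter, lower-dimension paths, which is the handle the group-contrast
  tests use. Defaults emulate a 2-minute 30 fps centroid track (3600
  frames); several tests use shorter paths (600–1500 frames) and smaller
  groups to keep the suite fast, with the sizes stated in the tests.

All generators are pure functions of their arguments including the
mandatory seed. What the CRW does *not* emulate: tracking noise, pauses
and head sweeps, arena boundary effects, and any genotype-specific
movement structure — so passing the group-contrast tests demonstrates the
statistical machinery, not a biological claim.

## Statistical protocol

Group comparison forms one-way ANOVA residuals (value minus group mean),
applies Shapiro–Wilk at α = 0.05, and selects Student's t-test when
residuals pass and the two-sided, tie-corrected Mann–Whitney U test when
they fail. Pairwise p-values against the designated control (first group
by default) are reported raw; Bonferroni adjustment is available but off
by default. The null calibration test (identical generator parameters,
200 seeded replicates, 30 paths per group, 600 frames per path, dimensions
from the direct temporal estimator over δ = 1..20) rejects at 3.5%,
consistent with the nominal 5% level.

## Known limitations

- Exact counting is specified for planar curves only; the crossing
  construction does not generalize as-is to d > 2.
- The temporal estimator assumes (approximate) stationarity of the
  displacement process; strongly heterogeneous paths violate this and
  show up as low r² in the α fit.
- The elbow is undefined for paths whose counting curve has no saturation
  regime within S0 (e.g. very short paths); the pipeline surfaces these as
  stage-tagged errors rather than guessing.
- Estimates at a single finite scale inherit grid-placement uncertainty of
  order 1–2% (see the perturbation module); comparisons across groups
  should rely on ensembles of paths, not single trajectories.
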