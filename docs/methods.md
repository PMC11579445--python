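# Methods

This note documents the models, conventions and numerical choices behind
`crowntrack`, and what the synthetic-scene validation does and does not
demonstrate about real survey data.

## The synthetic woodland generator

The generator emulates the study system the pipeline is designed for:
semi-arid, open-canopy woodland of sparse, single-stemmed trees surveyed
twice by ALS roughly a decade apart.

**Terrain.** A gently tilted plane (slope 0.004) with a Gaussian-profile
drainage channel (default amplitude 4 m, width 30 m) incised along a sine
curve, plus smooth correlated microtopography (sd 0.25 m, 40-m
correlation), at 5-m resolution. This produces the spatial TWI contrast
(channel vs interfluve) the demographic models need.

**Trees.** Stem density defaults to 22 trees ha⁻¹ (observed densities in
such old-growth stands span roughly 15–34 ha⁻¹). Heights are lognormal
(median 10 m, log-sd 0.35) truncated to 4–22 m; crown diameter follows
CD = 1.45·H^0.90 with lognormal scatter (log-sd 0.15), chosen so a
mean-height tree carries a crown of ~125 m², matching the size structure
the pipeline targets. Placement is dart throwing under a hard-core rule —
stem separation at least R_i + R_j + gap — so crowns never overlap; the
default gap is 2 m. Dart throwing jams well below hexagonal packing, so
configurations demanding 5-m gaps are run at 15 trees ha⁻¹ (still within
the observed range); the generator fails loudly if it achieves < 80% of the
target density.

**Demography.** Per-decade height growth decays exponentially with log
size (0.55 m/decade for the smallest trees); crown-area growth rises
sigmoidally from 7 to 16 m²/decade; death/dieback is logistic in log size
(≈ 11% per decade at the mid size, rising toward small trees) — all with
additive linear effects of TWI (growth up, mortality down with wetness) and
neighbourhood crowding, centred on scene means. Interval quantities scale
linearly from per-decade rates except death probability, which compounds:
p_interval = 1 − (1 − p_decade)^(T/10). A quarter of "died" trees are
rendered as severe dieback — the crown persists with half its radius
(−75% area) — because the pipeline treats death and severe dieback as one
class and must see both forms.

**Rendering.** Each live crown is a paraboloid cap,
z(r) = H − (H − 0.4·H)(r/R)², rasterised at 0.5 m with pixel = max over
crowns, additive Gaussian noise (default sd 0.15 m) clipped at zero. The
paraboloid guarantees one local CHM maximum per tree, which is the
segmentation model's core assumption. Pulse-density fields are smooth
Gaussian random fields anchored exactly at the survey means (21.4 and
23.6 pulses m⁻²). All streams derive from a single seed via named
substreams, so scenes are bit-reproducible.

**What the generator does not emulate:** within-crown CHM texture of real
eucalypts (the noise model is an uncalibrated stand-in), occlusion and
scan-angle effects, multi-layer canopies, and co-registration error beyond
i.i.d. pixel noise. Passing recovery tests on these scenes therefore
demonstrates algorithmic correctness — not field-accuracy of segmentation
on real canopies, where crown shapes are irregular and adjacency is harder.

## Segmentation

Seeding follows the local-maxima convention: a pixel ≥ 4 m is a seed when
it is the strict maximum of a circular window of diameter
w(h) = c·h^d + floor (defaults c = 1.45, d = 0.90, floor = 1.5 m — the
generator's own crown allometry, since the window should scale with the
crown a tree of that height can carry). Ties go to the first pixel in scan
order and are recorded. The two passes scale the window by 1.3 (broad) and
0.6 (small); the broad pass is masked out of the CHM before the small pass
runs.

Growth is a single global height-descending queue over all regions
(ties by insertion order): a popped pixel joins its region iff it is
unclaimed, exceeds th_seed × seed height and th_cr × the region's current
mean height, and lies within the allometric crown-diameter cap
(1.5 × w(seed height) / 2) of the seed; 4-connectivity for growth,
Euclidean discs for windows. th_seed = 0.45 and th_cr = 0.55 are the
long-standing defaults of this algorithm family and are exposed in
`SegmentationParams`. Crowns are polygonised exactly (union of pixel
squares) so polygon area ≡ pixel count × pixel area and IoU is exactly
testable; crowns failing "taller than 4 m and crown area > 9 m²" (strict
inequalities) are dropped.

A deliberately naive re-implementation (linear-scan frontier selection, no
heap) lives in `crowntrack.reference` and must agree **exactly** with the
production grower; the same file carries a sorting-based D8 flow
accumulator used to validate the terrain router.

## Matching and fate classification

Containment is boundary-exclusive (a centroid on a shared boundary belongs
to no crown) — an arbitrary but deterministic tie rule. The ≥ 30% decline
rule uses relative loss (v₁ − v₂)/v₁ with the boundary inclusive, and
height or area decline each suffice. Unmatched first-survey crowns are
overlaid on both CHMs; only those whose in-polygon maximum collapsed by
≥ 30% are deaths — the rest are presumed segmentation omissions and
excluded ("unresolved") rather than silently counted either way. The
mean-CHM height per crown is stored alongside the maximum for comparison,
but the maximum is the operative height definition. Recruitment (crowns
present only in the second survey) is counted but never converted to a
rate: small trees can cross the size threshold and die within one census
interval, so a two-survey design underestimates recruitment in a way no
correction inside this package could fix.

Because "% per decade" is not a unique convention for a 9-yr interval, the
mortality summary reports three variants side by side: the raw interval
fraction, linear scaling (×10/T), and compound scaling
(1 − (1 − m)^(10/T)).

## Allometry and biomass accounting

DBH (cm) = 0.519·(H·CD)^0.890·1.002 and AGB (kg) = 0.133·DBH^2.375·1.067,
with the correction factors being Baskerville-type log-back-transform
adjustments. The (H·CD)^exponent grouping follows the crown-allometry
framework these coefficients come from. Dead trees contribute their
first-survey biomass to stocks and lose all of it (AGB₂ = 0); ambiguous and
unresolved trees are excluded from every rate, never zero-filled. Gains are
survivors' summed biomass change, losses the dead trees' (negative), and
net ≡ gains + losses holds to machine precision by construction — it is
asserted, not rounded into place. Equal-width log bins serve the rate
curves (the size distribution is strongly right-skewed); decile bins serve
stock/flux partitioning so classes are directly comparable. A value tied
with a percentile cut goes to the lower bin.

Mortality per size class uses the saturated binomial fact that the GLM
fitted probability is the bin proportion; its 95% CI is computed on the
logit scale (delta method), falling back to the Jeffreys interval in bins
with zero (or all) deaths where the logit interval degenerates.

## Terrain and neighbourhood covariates

TWI = ln(a / tan β): contributing area per contour width (one cell) over
central-difference slope, floored at tan β = 0.001 to keep the index
finite on flats. Routing is multiple-flow-direction — each cell sends its
accumulation to all lower 8-neighbours with weights proportional to the
gradient — after priority-flood sink filling with a 10⁻⁶ gradient. MFD
approximates the hydrological behaviour of the wetness indices used in
ecohydrology; D8 is provided for oracle testing, and mass conservation
(total outflow = total cell area) is verified to 10⁻⁹ relative error.

Neighbourhood height is the mean CHM value in a 25-m buffer around the
crown perimeter, excluding the focal crown's own pixels (the buffer is
"around the perimeter"; the inclusive variant is a switch). Edge crowns use
the clipped buffer. Pulse-density difference is sampled at the crown
centroid.

## Driver models

The GAMs use a P-spline smooth in log tree size: 10 cubic B-splines on
equally spaced knots with a second-order difference penalty. The penalty's
null space (constant + linear) joins the fixed effects with the
standardized linear covariates; the whitened range space enters as i.i.d.
random effects whose variance ratio is chosen by **exact Gaussian REML**
(profiled scale, Woodbury identities on the q ≈ 8 random columns) — for
the binomial model, by REML on the IRLS working response at each step
(penalized quasi-likelihood). Standard errors and the smooth's effective
degrees of freedom come from the Bayesian posterior covariance of the
penalized fit, the usual convention for penalized regression. On a common
test problem the linear-term estimates and standard errors agree with
mgcv's REML fits to ~4 decimals (an independent cross-check in the test
suite); the smoothing level itself differs slightly because the bases
differ.

Degenerate cases raise rather than warn: a constant covariate (rank
deficiency), a one-class binomial response or |η| > 30 at convergence
(separation), IRLS non-convergence. Forcing the variance ratio to ~0
collapses the smooth to its null space and must reproduce OLS on
[1, log size, covariates] — asserted against statsmodels to 10⁻⁶.

Conditional prediction curves sweep size across the 5th–95th percentile at
the 5th/mean/95th percentile of one covariate, others at their means and
pulse difference fixed at raw zero (standardized through the stored
constants); sizes outside the training range are flagged, not silently
extrapolated. Residual spatial structure is screened with a binned Moran's
I correlogram against a seeded permutation envelope (199 permutations,
2.5%/97.5% bounds); distance classes with fewer than two pairs are dropped
with a warning.

## Landscape aggregation

Hectare cells are anchored at the raster origin; partial edge cells are
kept with their true pixel counts and flagged rather than silently
averaged. Canopy cover uses the strict "> 4 m" reading of the inclusion
threshold. Per-decade rates scale linearly (×10/T). Nodata pixels leave
the denominator; an all-nodata cell is flagged, not zero. Rate-map
correlations are reported with both Pearson and Spearman coefficients,
since either convention is defensible for these skewed per-cell rates.

## Problem sizes and configurations used in validation

The test-suite and acceptance scenes are 25 ha (500 × 500 m, a 1000 × 1000
CHM) — large enough for ~350–580 crowns per scene while keeping a full
multi-scene validation run in minutes. Benchmark scenes demanding 5-m
crown gaps run at 15 trees ha⁻¹ (hard-core feasibility, above); the study
configuration in `analysis/` uses 22 ha⁻¹ with 2-m gaps and 0.15-m CHM
noise. Statistical recovery uses ~5000-tree tree-table scenes (no
rendering) and 50 replicates for interval-coverage assessment.

## Known limitations

- Pixel-space exactness is a design choice: crown polygons are unions of
  pixel squares, so areas are multiples of 0.25 m² and boundaries are
  staircase-shaped. Smoothing would look nicer and test worse.
- The PQL binomial fit shares penalized quasi-likelihood's known small-n /
  rare-event bias; at the sample sizes used here it is negligible against
  sampling error.
- The generator's mortality and growth are stationary in time and
  unconditionally independent across trees given covariates; clustered
  disturbance (e.g. a storm track) is not simulated.
- CRS handling is deliberately minimal (a label carried through GeoTIFF
  tags); reprojection is out of scope.
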