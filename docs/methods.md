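# Methods

## Estimation model

The package performs model-based (as opposed to design-based) survey
inference: observations are treated as realizations of the stochastic
model

Y = Σ_{j} β_j x^j + ε,  ε ~ N(0, σ²),

with Y aboveground biomass density (Mg/ha) and x the lidar-derived
Lorey's height (m) of a population element — the land associated with
one pixel of the forest mask. The default specification is the
single-term, no-intercept quadratic Y = βx², on the physical ground that
a forested plot with no biomass should return no height. Fitting is
ordinary least squares on the training sample S2 (m plots), which under
the Gaussian error coincides with maximum likelihood; the residual mean
square uses m − p degrees of freedom and the parameter covariance is the
standard mse·(XᵀX)⁻¹.

The population mean over the N forest pixels is estimated by the mean of
model predictions over the application sample S1 (n elements, heights
only). Its estimated variance is the sum of

* a **sampling summand**, s²(Ŷ)/n — the simple-random-sampling variance
  of a sample mean, applied to the n predictions. No finite-population
  correction is applied by default (an optional flag exists): the
  intended regime is n ≪ N.
* a **model summand**, Σ_k Σ_l Ĉ(β̂_k, β̂_l)·x̄*_k·x̄*_l, where x̄*_k is
  the S1 mean of x^k — the parameter uncertainty of the fitted model
  propagated through the S1 design moments. For the no-intercept
  quadratic the double sum has a single term, V̂(β̂)·(x̄²)².

Assumptions inherited by any user of the estimate: the model form is
correct for the whole domain; heights are measured without error; the
S1 elements are treated as an independent simple random sample (no
spatial autocorrelation correction). S1 heights beyond the S2 training
range are predicted anyway, with a logged warning listing them, rather
than truncated — the model is assumed valid over the population. The
estimator also carries a bias term equal to the population mean of the
(unobservable) per-element model errors; its expectation is zero and it
is not estimable from the data, so it is documented but has no
computation.

## Sample design

The design maps the 2-D domain to 1-D with a space-filling curve,
segments the resulting number line into equal-length (hence equal-area)
cells, and keeps one shot per cell:

1. **Ordering.** The default curve is the base-3 serpentine Peano curve,
   built recursively from the 3×3 boustrophedon generator; reflections
   of the sub-blocks (columns flipped in odd block-rows, rows flipped in
   odd block-columns) keep consecutive cells 4-adjacent at every level.
   A Hilbert curve is available behind the same contract; any
   self-similar, adjacency-preserving curve works, and the package makes
   no claim of matching the pixel order of any other implementation.
   The grid is embedded in the smallest curve square covering
   max(rows, cols), anchored at the top-left with a fixed generator
   orientation — arbitrary choices, frozen for reproducibility. The
   number line is the restriction of the full-grid visit order to forest
   pixels, which preserves relative order under any sub-masking.
2. **Segmentation.** Among segmentations of the circular number line
   into n = ⌊N/l⌋ contiguous segments of length l (remainder dropped at
   the rotated end), the search returns the smallest l — ties broken by
   the smallest rotation offset s — such that every segment contains a
   shot-bearing pixel. Offsets are realized as rotations of the whole
   line, which makes all starting points structurally identical; the
   remainder therefore always sits at the rotated end. Half the longest
   circular shotless gap is a useful mental lower bound for l (a
   shorter segment would typically fall entirely inside the gap), but it
   is not exact: the dropped remainder can absorb part of a gap, so in
   edge cases the true minimum sits below it. The implementation
   therefore scans l upward from 1; candidate lengths are rejected in
   O(N) time via a cycle decomposition of the offset lattice (offsets
   stepping by l modulo N form gcd(l, N) cycles; an offset is viable iff
   the next shotless window on its cycle is at least n steps ahead,
   which one reversed running minimum answers for all offsets at once).
   Termination is guaranteed because l = N is viable whenever any shot
   exists.
3. **Drawing S1.** Two independently seeded randomizations: first, where
   k > 1 shots share a pixel, each survives as the pixel's
   representative with probability 1/k; second, within each segment one
   shot-bearing pixel is chosen uniformly. Independent streams mean
   either stage can be re-randomized alone. Given the seeds, the entire
   chain is deterministic, and every exported artifact records its seeds
   and a configuration hash.

The one-per-equal-area-cell sample is *treated* as a simple random
sample downstream, mirroring the precedent of national inventory hexagon
designs that retain one plot per cell; the package documents this
design-equivalence argument but does not prove it.

## Geodata conventions

Pixels are square, in a projected equal-area CRS with meter units;
inputs whose cell size is below 1 m are rejected as likely geographic
(degree) grids rather than silently reprojected. Pixel footprints are
half-open in both axes, so a shot on a shared edge belongs to exactly
one pixel and shots on the far east/south domain boundary fall outside.
Rasters are exchanged as single-band integer ESRI ASCII grids; mask
round trips are bit-exact. Categorical resampling (e.g. a 1 km land
cover product to the 230 m processing resolution) is nearest-neighbor —
the only class-preserving choice — with output dimensions
round(dim·res_in/res_out). The forest class codes are configuration, not
constants, so a 0/1 synthetic mask and a multi-class land-cover product
are handled identically. Shots are filtered on their quality flag, then
to the half-open extent, then to forest pixels.

## Synthetic data: what it emulates, and what not

The generator reproduces the features of the real acquisition that the
method's validity depends on:

* a **clustered binary forest mask**: smoothed white noise thresholded
  at the quantile matching the target forest fraction (default 0.55,
  clustering scale 1200 m);
* **ground tracks**: straight lines at a 94° azimuth from north (or its
  descending mirror), shots every 172 m along-track, with across-track
  placement either uniform or clumped around a few cluster centers
  (default 5 clusters, 1500 m spread) to mimic the arbitrarily uneven
  track density of the real archive — the pathology that motivates the
  design. On a coarse reference grid the per-cell shot counts have a
  coefficient of variation well above 0.5, i.e. the raw pattern is far
  from any uniform random sample;
* **heights**: a Gaussian random field (default mean 24 m, sd 7 m,
  correlation length 900 m), truncated at zero;
* **biomass**: Y = βx² + ε with β = 0.3717 Mg/ha/m² (the published
  California coefficient) and σ = 60 Mg/ha, truncated at zero — at
  default heights the truncation affects well under 0.1% of draws;
* **training plots**: hosts sampled without replacement from the shots,
  plot centers jittered uniformly within a 120 m co-location radius,
  plot height read from the height field at the jittered center and
  biomass generated from that height — so training pairs carry
  co-location displacement while the height–biomass relation itself
  stays exact.

The default domain is 80×80 pixels of 230 m (3–4 thousand forest
pixels), a deliberate desk-scale choice that keeps a full synthetic run
under a second while exercising every code path; the ordering,
segmentation and estimation code paths are identical at any N. What the
generator does **not** emulate: real waveform noise or height
measurement error, topographic effects, cloud-driven quality flags,
regional variation in the height–biomass relation, and spatial
autocorrelation of model errors. Passing tests therefore validate the
sampling design and the variance arithmetic under the model's own
assumptions — they say nothing about how well the quadratic model fits
any particular forest.

## Monte Carlo validation

`run_monte_carlo` regenerates **everything** each replicate — landscape,
height field, tracks, pixel collapse, S1 draw, training plots — runs the
full chain, and compares the estimate against that replicate's true
forest-pixel mean of βx². Regenerating the landscape (rather than only
re-randomizing the sampling stages on one fixed landscape) is what makes
the check a validation of the estimator rather than of one landscape
draw: on a single fixed landscape the fixed set of shot-bearing pixels
induces a replicate-invariant offset between the reachable sample and
the all-pixel truth, and coverage would measure that accident.

The validation uses a deliberately *well-specified* configuration
(uniform track density, 40 tracks, 300 m height correlation length):
the regime in which shot placement is effectively exchangeable with
respect to heights and the one-per-cell draw genuinely behaves like a
simple random sample — which is precisely the assumption the variance
formula makes. Under it, 1000 replicates give 95% interval coverage
within [0.93, 0.97] and bias within Monte Carlo noise of zero; the mean
estimated SE slightly exceeds the empirical spread, consistent with the
mild conservatism of assuming simple random sampling for a spatially
balanced design.

## Numerical and degenerate-case choices

* Segmentation tie-break: smallest l, then smallest offset; both checked
  against exhaustive (l, s) enumeration in the tests.
* A shotless number line, an empty forest mask, an empty retained-shot
  table, all-zero training responses, m ≤ p training sets and
  rank-deficient designs all raise typed errors rather than degenerate
  results; pipeline stages prefix errors with the stage name.
* The sampling summand uses the n−1 divisor; with n = 1 it is undefined
  (NaN) rather than zero.
* Uniformity of the random stages is enforced statistically in the
  tests (binomial/multinomial 3σ bands, chi-square goodness of fit).

## Known limitations

* The design-equivalence of the one-per-cell sample to SRS is argued,
  not proved; with strongly spatially structured biomass the SRS
  variance is conservative.
* Minimal-l segmentation is recomputed from scratch per dataset; the
  search is O(N) per candidate length, which is ample for millions of
  pixels but the implementation holds the full curve in memory (a size
  cap guards against absurd levels).
* ESRI ASCII is the only raster format; CRS metadata beyond cell size is
  not interpreted, and reprojection is out of scope.
* The model summand propagates parameter uncertainty only; model-form
  misspecification and height measurement error are assumed away, as in
  the estimation framework itself.
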