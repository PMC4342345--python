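# Methods

`permeascape` infers which land-cover classes facilitate or impede gene
flow from the joint geometry of genetic population structure and a
categorical land-cover map. This note documents the model and the
procedure as the package implements them, the synthetic data-generating
process used to test the chain end to end, and the numerical and design
choices a user or maintainer should know about.

## The analysis chain

**1. Populations and membership surfaces.** The unit of analysis is a
study cell (~23 km², 30 m land-cover pixels). Within a cell, individuals
genotyped at microsatellite loci are partitioned into k genetic clusters
("populations"), and a 100×100-pixel grid bounded by the outer sample
sites carries, per pixel, a posterior probability vector of membership
in each cluster. The package accepts externally produced partitions and
per-cluster probability rasters; it also provides its own deterministic
stand-in (below). Spatially explicit Bayesian MCMC clustering itself is
out of scope.

**2. B and W segments.** Pairwise Euclidean distances are computed
between sample sites within each population; populations holding a
single site contribute no distances. Let *m* be the median
within-population distance (by default pooled over all multi-site
populations in the cell; a per-pair scope is available, since the two
plausible readings of the rule differ — see "Open choices"). For each
unordered pair of populations, the minimum-distance site pair is found;
if that distance is strictly below *m*, the pair is joined by exactly
one **B** ("between") segment — two populations closer than typical
within-population site spacing imply a barrier rather than isolation by
distance. Each population touched by a B segment contributes exactly one
**W** ("within") segment: the within-population site pair whose length
most closely matches the joining B segment's length (smallest mismatch
over all joining B segments if several). Multi-site populations touched
by no B segment use a fallback target length of 776 m — the study-wide
mean B-segment length. Single-site populations yield no W segment. Ties
anywhere resolve to the lexicographically smallest site-id pair.

**3. Composition at multiple bandwidths.** Each segment is a rectangle
running exactly site-to-site (no end caps) at widths 3, 10, 25, 50,
100, 200, 400 and 1000 m. A land-cover pixel belongs to the rectangle
if its center falls inside: closed along the axis, half-open across it
(the positive-side boundary included), so an axis through pixel centers
selects exactly width/resolution pixel rows and the selection is
deterministic under ties. A rectangle thinner than the pixel grid falls
back to the two endpoint pixels, so the pixel set is never empty.
Composition is the per-class pixel fraction over the nine classes
(forest, non-treed corridor, treed corridor, grassland, shrubland,
water — open water pooled with wetland, urban, road, agriculture). The
segment's mean membership probability is the arithmetic mean of the
per-pixel **modal** probability (maximum over the k clusters) over the
same pixel set, with nearest-neighbor lookup from land-cover pixel
centers into the 100×100 surface grid and edge clamping outside its
bounding box. The modal reduction is a deliberate choice: it is the only
single-valued per-pixel quantity defined for every pixel of a B segment
spanning two clusters; a named-cluster slice is available instead.

**4. Regressions with bootstrap-wrapped stepwise selection.** Segments
pooled across cells form one analysis set per width. Two model families
share the harness, with the eight land-cover proportions excluding
agriculture as predictors (agriculture is the complement of the rest in
this mosaic and is nearly collinear with forest):

* **logistic** — response is segment category (B = 0, W = 1), fit by
  IRLS; reported per width: null and residual deviance, percent deviance
  explained = 100·(D₀ − D)/D₀, AIC = deviance + 2·(coefficients);
* **linear** — response is arcsin(√p̄) of the segment's mean membership
  probability (variance-stabilising for proportions; an
  Anderson–Darling normality test with the case-3 p-value approximation
  is provided to motivate the transform); reported: R², adjusted R²,
  overall F-test p, Gaussian AIC with the profiled variance.

Stepwise selection starts from the full model; at each step the single
variable removal or re-addition with the largest AIC decrease is
applied, stopping at a local AIC optimum (intercept always kept). The
whole fit-then-select step runs inside a nonparametric bootstrap: B
resamples of the n segments with replacement (default B = 1000,
unstratified, matching resampling of the full dataset; a
stratified-by-category option exists for tiny n). Per width and
variable the summary reports the retention count, the conditional mean
and SD of the coefficient over iterations where it was retained, a
percentile 95% CI, and the mean per-coefficient p-value; a variable is
"selected" when retained in at least 900 of 1000 iterations.
Conditional (not shrunk-toward-zero) means are reported because a
single estimate per retained variable is wanted; this is a convention
and is flagged as such.

**Separation.** Near-separable resamples are common in this problem —
B/W category is close to a deterministic function of composition. A
separated logistic fit terminates on the numerical deviance criterion
(as GLM software does), is flagged `separated`, and is accepted and
counted by the bootstrap; its coefficients are not interpretable but
its classifications are. A strict mode redraws separated resamples
instead; it is only usable when the data are far from separation.
Resamples with a single response class, or true non-convergence, are
always redrawn (bounded at 10·B attempts).

**5. Validation.** Within each bootstrap iteration, 20% of that
iteration's segments are drawn without replacement, 1000 times, and
scored against the iteration's own model: a logistic prediction is
correct when the predicted category (W iff fitted probability strictly
above 0.5) matches the observed one; a linear prediction is correct
when the observed transformed probability lies inside the t-based 95%
prediction interval ŷ ± t·s·√(1 + leverage), evaluated on the
transformed scale. Proportions are aggregated over all validated
segments with a binomial normal-approximation CI. "20% of the
individuals" is read as 20% of the segments — segments are the analysis
units and the reported validation totals are consistent with that
reading. Scoring against the iteration's own (in-bag) model follows the
described procedure; an out-of-bag option is provided, off by default.

## Population-genetic summaries

Per locus × population: typed count N, allele count Na, observed
heterozygosity, unbiased expected heterozygosity 2N/(2N−1)·(1 − Σp²),
allelic richness by hypergeometric rarefaction to g genes (g defaults
to twice the smallest typed sample), and F_IS = 1 − Ho/He with a 95% CI
from permuting alleles among individuals within the population (1000
permutations by default). Monomorphic loci report F_IS as missing, not
zero. Pairwise F_ST is the Weir–Cockerham (1984) θ̂, combined over
alleles and loci as a ratio of summed variance components; significance
comes from shuffling individuals between the pair (1200 randomizations
by default), and every permutation p-value in the package uses the
(b+1)/(m+1) estimator so p = 0 cannot occur. Isolation by distance is a
simple Mantel test of F_ST/(1 − F_ST) against Euclidean distance:
Pearson r of the off-diagonal upper triangles, one-sided p from
simultaneous row/column permutations; pairs with θ̂ = 1 (infinite
linearisation) are excluded with a warning. Loci are handled per locus
for missing data: a locus drops out of a pair only where a population
has no calls at it.

## The assignment-surface stand-in

The package's own membership surfaces are deterministic and
dependency-light. Individual posteriors come from leave-one-out
allele-frequency assignment: per-population allele frequencies with an
additive pseudo-count per allele, the focal individual's alleles
removed from its own population's counts, uniform prior over the k
populations. The surface interpolates individual posterior vectors by
power-2 inverse-distance weighting onto the 100×100 grid over the site
bounding box, renormalised per pixel; a pixel coincident with an
individual takes that individual's vector. Plain IDW lets a densely
sampled population dominate remote pixels by count alone, so optional
per-individual weights equalise each population's total mass
(`population_weights`); the pipeline uses them by default. Individuals
with no typed locus get the uniform vector and are flagged.

## Synthetic scenarios: what they emulate and what they do not

The generator reproduces the study conditions so the chain can be
tested without any external data:

* **Land cover** — a patch mosaic with nuclei on a jittered coarse
  lattice (default every 6 pixels), nucleus classes assigned by
  largest-remainder quota and pixels taking the nearest nucleus's
  class. Defaults: 88% agriculture, 8% forest, the remaining 4% split
  evenly over the seven minor classes; realised fractions track targets
  within ±5 percentage points on ≥160×160 rasters. Roads appear as
  patches, not networks — a known unrealism.
* **Territories** — k contiguous territories grown by cost-weighted
  flood fill (multi-source Dijkstra) from spaced seeds, with elevated
  cost across barrier classes (defaults: water ×25, road ×10,
  urban ×5), so boundaries tend to co-locate with barrier habitat.
  Cluster-size and territory-shape distributions are conventions, not
  calibrations.
* **Sites** — stratified-random at pixel centers: forest, grassland and
  water 27.8% of sites each, urban 13.9%, agriculture 2.8%
  (largest-remainder rounding; empty strata reallocate their quota with
  a warning), at most 45 sites per cell; forest sites are additionally
  spread over patch-size classes (<5, 5–50, >50 ha) where present.
* **Genotypes** — the F-model: per locus, ancestral frequencies are
  symmetric-Dirichlet(1); population frequencies are Dirichlet around
  the ancestral vector with concentration (1−θ)/θ, so θ is the expected
  Weir–Cockerham differentiation (verified unbiased within ±0.02 at
  θ = 0.1 over 50 replicates); diploid calls are drawn per individual
  from its population's frequencies. 12 loci, 8 alleles per locus by
  default. No coalescent or individual-based dispersal simulation:
  drift acts at the allele-frequency level only.
* **Surfaces** — per-pixel cluster logits decay with distance to each
  territory (scale 300 m); the true cluster's logit is shifted by the
  local 3×3 land-cover composition weighted by configurable true
  coefficients, plus Gaussian noise (sd `noise_sd`), then softmaxed.
* **Segment-level datasets** — for effect-recovery studies a direct
  generator draws each segment's composition as an endpoint-anchored
  mixture (each end contributes half of a site-stratum one-hot; a
  logistic-normal matrix mixture fills the rest; end weight uniform on
  0.3–0.7), reflecting that segments join sites placed disproportionally
  in natural cover. The B/W category is a **liability threshold**: W iff
  intercept + Σ coefᵢ·xᵢ + ε > 0 with ε ~ N(0, noise_sd = 0.2), the
  intercept calibrated to a 23:47 B:W split at n = 70. Category in the
  emulated system is a geometric fact — whether a genetic boundary
  crosses the corridor — so it is near-deterministic in composition;
  noise_sd controls boundary mislabelling, not an independent coin flip
  per segment. A Bernoulli-logistic response was considered and
  rejected: it caps the detectability of a +2.5 coefficient on a
  proportion far below the retention behaviour this analysis design
  exhibits. Membership responses are generated on the arcsin-√ scale
  with scaled-down coefficients plus Gaussian noise, then
  back-transformed.

Passing tests on these scenarios show the chain recovers known effects
under the stated generating process; they do not show robustness to
spatial autocorrelation of real genotypes, MCMC uncertainty in the
partition, land-cover misclassification, or linear road networks, none
of which the generator produces.

## Numerical choices

* IRLS with step-halving (deviance kept monotone), relative deviance
  tolerance 1e-8, 100-iteration cap; a deviance below 1e-3 is treated
  as (quasi-)separation and iteration stops — further steps only
  inflate coefficients. Singular information matrices fall back to the
  minimum-norm Newton step.
* Inside the stepwise search, candidate models are scored by a fast
  path computing only the deviance/RSS and AIC; the final model is
  refit with full inference statistics. The search counts parameters
  per column, so exactly aliased duplicates are stepped out one by one;
  the final linear fit drops any remaining aliased columns with a
  warning. Rank-deficient linear fits report NaN for dropped columns.
  A move cap of max(2p², 10) guards against cycling.
* Gaussian AIC is n·ln(2π·RSS/n) + n + 2·(coefficients incl.
  intercept), matching the profiled-variance log-likelihood convention
  of standard OLS summaries; logistic AIC is deviance + 2·(coefficients).
* Rectangle membership uses a 1e-6 m geometric tolerance; rasters are
  row-major from the top-left origin; coordinates are continuous meters
  in a projected CRS.
* Master seed → per-stage RNG streams via (seed, CRC32(stage name)), so
  stages rerun reproducibly in isolation and everything is a pure
  function of (inputs, config, seed).

## Problem sizes in the shipped tests and reproduction script

The defaults mirror the analysis design (B = 1000, retention 900,
1 000 000 validation subsamples per width). The test suite and
`scripts/acceptance.py` run the same machinery at study sizes chosen to
keep the whole suite comfortably interactive: effect recovery uses 100
fresh 70-segment scenarios at B = 100 (success = correct signs and
true-effect variables retained at rates no lower than any no-effect
variable; measured 95–97/100), F-model recovery uses 50 replicates of
2×200 diploids × 12 loci, coverage uses 2000 fresh test points,
permutation-null calibration uses 500 draws at 99 permutations, the
surface-recovery check uses 20 replicates at the 45-site design cap
with two balanced territories, and the pipeline demo pools 5 synthetic
cells at B = 20. A reduced `RunConfig.ci_profile()` (B = 100, 50
validation repetitions) ships for quick end-to-end runs.

## Open choices and limitations

* **Median-distance scope.** The B-segment threshold defaults to the
  global median over all multi-site populations; a per-pair scope is
  implemented. Neither is asserted to be the original computation — the
  two descriptions of the rule conflict.
* **Rectangles end at the sites.** No evidence was found that segments
  extended beyond their endpoint sites; none is added.
* **Modal probability for B segments** is a documented decision, not a
  statement of the source procedure (see step 3).
* The printed null deviance (87.350) is not the analytic binomial null
  for a 23/47 split (≈88.64); the bootstrap summary therefore reports
  both the per-iteration analytic null and its bootstrap mean rather
  than asserting either.
* In-bag validation overstates out-of-sample accuracy; the out-of-bag
  option exists precisely to quantify that gap.
* No least-cost-path or resistance-surface corridors, no mixed models,
  no spatial-autocorrelation correction, no HWE/LD exact tests, no
  null-allele estimation.
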