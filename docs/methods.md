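# Methods

`slp-biogeo` implements a genus-level comparative analysis of a rare binary
floral trait — style-length polymorphism (SLP) — against two biogeographic
hypotheses: that the trait tracks tropical distributions (where specialised
pollination is more prevalent) and that it tracks biodiversity hotspots /
high species richness (where a labile trait has more chances to arise).
Every stage can run on synthetic data generated by the package itself, so
the statistical machinery is testable without any download.

## Biogeographic coding

Regions (botanical countries) carry a latitudinal extent, a centroid and a
precomputed hotspot-overlap flag.  A region is *tropical* when its extent
intersects the closed band ±23.45° (23°27′).  A genus is coded tropical
(resp. hotspot) when at least a threshold fraction — default 0.50, with
0.70 as a sensitivity setting applied to the tropical coding only — of its
occupied regions carry the flag; a tie at exactly the threshold codes as
state 1 ("at least" rule).  Genus distribution centroids are the centroid
of the convex hull of occupied-region centroids computed on raw (lon, lat)
planar coordinates: one region maps to its centroid, two regions or
collinear sets to the midpoint of the extremes (the degenerate hull), three
or more to the hull's area centroid.  Ranges spanning the antimeridian are
not re-wrapped; centroids of trans-oceanic ranges may fall in the ocean,
which is tolerated because the centroid only feeds a distance-based
autocorrelation statistic.  Hotspot flags are input data, not computed from
hotspot polygons.

## Phylogenetic signal (D statistic)

For a binary trait on a rooted tree, each internal node is assigned the
unweighted arithmetic mean of its children's values (polytomies average
over all children; branch lengths do not enter this sweep), and the
observed statistic is the sum over edges of |child − parent|.  This sum is
scaled between the means of two simulated references at matched prevalence:

* **random**: uniform permutations of the observed states across tips
  (expected D ≈ 1);
* **Brownian threshold**: unit-rate Brownian motion along branch lengths
  from a root value of 0, thresholded so that the k tips with the highest
  liabilities (k = observed count of state 1; ties broken by tip index)
  receive state 1 (expected D ≈ 0).

D = (d_obs − mean d_Brownian) / (mean d_random − mean d_Brownian).
`p_random` is the fraction of permutation sums ≤ the observed sum,
`p_brownian` the fraction of Brownian sums ≥ it.  Default 1000 simulations
per reference; the RNG seed is recorded in the result.  Because both
references are simulated with the same statistic, the calibration targets
(mean D within ±0.15 of 1 for shuffled traits and of 0 for
threshold-Brownian traits, over 200 replicates on 200-tip trees at
prevalence 0.1) are a genuine check of the simulation machinery rather
than of a tuned constant; the test suite verifies them at exactly those
sizes.

## Phylogenetic logistic regression

The trait is modelled with a logit link whose linear predictor carries a
latent phylogenetic effect:

    logit P(y_i = 1) = x_i' β + u_i,   u ~ N(0, Σ(α)),
    Σ_ij(α) = exp(−α d_ij) / (2α),

with d_ij the patristic distance.  Σ(α) is the stationary covariance of a
mean-reverting (Ornstein–Uhlenbeck) process with unit diffusion rate:
between-tip correlation decays as exp(−α d_ij), and the latent variance
1/(2α) vanishes as the rate α grows, so a large α recovers ordinary
logistic regression exactly.  This one-parameter coupling is what makes the
star-tree reduction structural rather than numerical: with no shared
history the profile pushes α to its upper bound and the latent term is
numerically zero.

Estimation maximises the Laplace-approximate marginal likelihood.  For
fixed α, (β, u) are found by damped Newton on the joint penalised
objective; when Firth stabilisation is on (the default), the fixed-effect
score carries the standard hat-value adjustment, guarding against
separation — relevant for a trait carried by a few percent of thousands of
genera.  α is profiled on a log scale within [1e-4/T, 1e4/T] (T = tree
height): a 7-point grid locates the optimum, a bounded scalar search
refines it.  Coefficient covariance uses the working GLS form
(X'(W⁻¹+Σ)⁻¹X)⁻¹, which reduces to the logistic information at α → ∞.

**Likelihood-ratio comparisons.**  Reported `logLik` is the unpenalised
Laplace likelihood, and α is always selected on it.  Partial R²lik
(`1 − exp(−(2/n)ΔlogLik)`) and AIC comparisons are computed from
*unpenalised* ML fits: evaluating the likelihood at Firth-shrunk estimates
introduces an offset that grows with model dimension and can push a full
model's likelihood below its own reduced model, destroying the nesting the
likelihood-ratio test assumes.  The pipeline therefore reports Firth
coefficients for inference alongside ML-based R²/AIC tables.  For a
covariate the reduced model refits without it (LR df = 1); for the
phylogeny component the reduced model is plain logistic regression with
identical predictors (df = 1, for α).

The three model configurations mirror the predictor-collinearity design:
{tropical, hotspot, richness}, {tropical, richness}, {hotspot, richness},
all with phylogeny, compared by AIC / ΔAIC / Akaike weights.  Species
richness enters untransformed.  α hitting a profile bound is reported via
`alpha_at_bound` (no signal detected is a legitimate outcome, not a
failure); `converged` reflects the inner Newton optimisation.

## Phylogenetic linear regression

Generalised least squares under Brownian covariance V = σ²C, with C the
matrix of shared root-to-MRCA path lengths; ML estimates (σ² with
denominator n), Gaussian log-likelihood, normal-approximation p-values.
Used for species richness ~ hotspot occupancy on the complement (non-focal
family) dataset.  The implementation is cross-checked in the test suite
against frozen reference values from an independent Brownian GLS fit
(ape::corBrownian + nlme::gls, ML), which reports σ² on a unit-diagonal
correlation scale (factor = tree height) and coefficient covariance with
an n−p denominator; the frozen test encodes both conversions.

## Spatial autocorrelation

The patristic distance matrix is squared elementwise, double-centred
(PCoA transform), and eigendecomposed; the trait is residualised by OLS on
the top k = 10 eigenvectors (configurable), absorbing phylogenetic
structure.  Moran's I of those residuals is computed under inverse-distance
weights between genus centroids (great-circle km on a 6371-km sphere by
default; planar degrees available for oracle tests).  Coincident centroids
(genera sharing identical region sets) receive the maximum finite weight,
preserving "closest = heaviest" without infinities; the count is recorded.
Null moments use the closed S0/S1/S2 forms; the default is the normality
assumption, with the randomization (kurtosis-corrected) variance and
row-standardised weights available — the latter two reproduce ape::Moran.I
exactly, as a frozen test verifies.  OLS (not logistic) residuals are the
default input, the conventional choice for Moran's I; Pearson residuals
from a logistic fit would be a drop-in substitute and the residualiser
accepts any aligned vector.

## Synthetic data generator

The generator emulates the structure the analyses assume, at configurable
scale (defaults in parentheses):

* **Tree**: forward-time Yule or birth-death simulation (Yule, 500 tips),
  stopped when the target tip count is alive plus one exponential waiting
  time; extinct lineages pruned; ultrametric by construction.
* **Regions** (120): latitudinal extents placed so ~`tropic_fraction`
  (0.5) intersect the band; hotspot flags drawn with overall probability
  `hotspot_fraction` (0.4), enriched 1.5× inside the band with the
  complement rate solved to keep the overall mean.
* **Occupancy**: each genus evolves a Brownian "home" (lon, lat) on the
  tree (tip SD ~30° lat / ~80° lon) and occupies the 1 + Poisson(4)
  regions nearest its home, so related genera share regions — reproducing
  the concern that phylogenetic signal in geography could masquerade as
  trait signal.
* **Richness**: lognormal (log-mean 2.5, log-SD 1.5), ceiled to ≥ 1 —
  median ~12 species with a heavy tail, the shape of real genus sizes.
* **Trait**: liability threshold `l = β₀ + β_t·tropical + β_h·hotspot +
  β_r·richness + signal_sd·BM`, state 1 where l > 0, with the Brownian
  term scaled to unit tip SD and centred across tips.  Centring removes
  the lineage-wide root draw, which otherwise swings prevalence between
  <1% and >30% across seeds and breaks subset analyses at desk scale; the
  intercept then controls prevalence (defaults β = (−2.5, 0.5, 0, 0.005),
  signal_sd = 1.5 → prevalence ~8–15%, a rare conserved trait).  A second
  mode draws independent Bernoulli outcomes from the logistic mean — the
  exact generating model of the logistic fitter — for calibration tests
  where recovered coefficients must match the truth, since the liability
  scale of a threshold model is not identified and only signs/orderings
  are recoverable from it.
* **Families**: tips grouped by the clade crossing a fixed fraction (0.35)
  of tree height, named F001… from largest down; the family with the most
  trait-positive tips plays the focal-family role in subset reruns.

What the generator does *not* emulate: real coastline geometry, region
adjacency, taxonomic error, and the extreme scale imbalance of the real
flora (13k genera, 368 regions).  Passing recovery tests therefore show
the estimators work under the assumed generating processes at hundreds of
tips, not that the empirical study's effect sizes are correct.

## Pipeline and problem sizes

`run_study` executes: coding at thresholds (0.5, 0.7 — the 0.7 rerun
applies to the tropical coding only, on the full dataset), exploratory
tests (2×2 chi-square with and without Yates correction — both reported,
since continuity correction is a convention choice; Welch t on raw
richness; VIF; phi), D for the trait and both geographic codings, the
three model configurations with AIC and partial R², focal-family
include/exclude subset reruns, richness ~ hotspot GLS on the exclude
subset, and the Moran stage.  Stage failures are isolated: every report
cell is populated or carries an explicit skip reason.  All randomness
derives from one seed via a seed sequence; reports are byte-identical
across reruns.

Default desk-scale sizes, chosen to exercise every stage in minutes on one
CPU: benchmark pipeline 500 genera; D calibration 200 replicates × 200
tips × 1000 simulations; recovery 100 replicates × 300 tips.  The
generator emits 2000+-tip datasets without issue for larger experiments.

## Known limitations

* The Laplace approximation can be optimistic for very sparse traits on
  small subsets; the Firth fit is reported alongside for such cases.
* Nesting of Laplace likelihoods across models is a property of the
  approximation at its optimum, not a theorem; the profile-on-likelihood
  design keeps violations at optimisation-noise level.
* Hull centroids on raw coordinates misplace antimeridian-spanning ranges.
* The D statistic's node-value sweep uses unweighted child means; branch
  lengths influence only the Brownian reference simulation.
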