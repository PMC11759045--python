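# Methods

`skyground` implements a plot-scale framework for comparing plant
biodiversity measured on the ground (species inventories, traits, a
time-calibrated phylogeny) with biodiversity estimated from the sky
(plot-level imaging spectroscopy). This note documents the models, the
numerical choices, and what the synthetic landscapes do and do not
emulate.

## Diversity metrics

All plot-level metrics live in the Hill-number / distance-matrix family so
that ground and spectral versions are mathematically analogous and
directly comparable.

**Taxonomic (and spectral-species) metrics.** With relative abundances
`p_i` (percent cover renormalized per plot; cluster proportions for
spectral species): richness `S` (q = 0), Shannon entropy
`H = -Σ p_i ln p_i` (q = 1), Gini-Simpson `D = 1 - Σ p_i²` (q = 2).

**Distance-based metrics.** Given a symmetric species distance matrix
(Gower distances on traits; patristic distances on the phylogeny;
Euclidean distances among vector-normalized pixel spectra):

- *MPD / MTD / MSD* — the unweighted mean over unordered member pairs.
  Communities of one member return a missing value, not zero.
- *PD / SD* — Faith's phylogenetic diversity, the branch length of the
  minimal rooted subtree spanning the community. The rooted convention is
  used: the stem path to the root is included and a single member scores
  its root-to-tip path. The spectral analog SD is the total branch length
  of a UPGMA dendrogram over the plot's pixels. ("Sum over pixels" is not
  a computable definition; the dendrogram length is the pixel-level
  translation of the PD row of the metric family, and we flag this reading
  prominently.)
- *Dispersion* `qD(.M) = 1 + (S - 1) · qE(T) · M'`, the effective number
  of distinct species. Distances are first scaled into [0, 1] by the
  global maximum within each dimension (cross-plot comparability; per-plot
  scaling is available via configuration). `m_i` is member i's mean
  scaled distance to the others and `M'` their mean. The Hill aggregation
  runs over the per-species dispersion profile `ω_i ∝ p_i · m_i`
  (abundance-weighted; the unweighted `ω_i ∝ m_i` variant sits behind a
  flag because both readings exist in the metric literature), with the
  q → 1 limit taken as `exp` of the Shannon entropy of ω. At q = 0 the
  profile reduces to counting, so `0D(.M) = 1 + (S - 1) M'`; for pixels
  with equal weights this is the only order computed, and it is exactly
  affine in MSD at fixed pixel count.
  Bounds: `1 ≤ qD(.M) ≤ S`, attained at zero distances and at maximal
  (all-ones) scaled distances with uniform abundances.

**Standardized effect sizes.** `z = (obs - mean(null)) / sd(null)` with a
taxa-label-shuffle null holding plot richness fixed (999 seeded replicates
by default), equivalent to drawing the same number of species uniformly
from the pool; negative values indicate trait/phylogenetic clustering,
positive values overdispersion. The null is vectorized over replicates.

## Spectral processing

Cleaning follows the standard imaging-spectroscopy order and each step
appends its parameters to a provenance log:

1. **Band filtering** removes the atmospheric water-absorption windows
   [1340, 1445] and [1790, 1955] nm (closed intervals) and all bands at
   ≤ 400 or ≥ 2450 nm.
2. **NDVI masking** removes non-vegetation pixels using window means at
   660–680 nm (red) and 800–860 nm (NIR); the threshold is 0.5 for
   high-cover plots and 0.2 for low-cover plots, with pixels exactly at
   the threshold kept. A plot is called high-cover when at least half of
   its pixels have NDVI ≥ 0.2 (the assignment rule is ours).
3. **Brightness masking** applies Tukey fences (k = 1.5) to per-pixel mean
   reflectance. Two-sided by default — the low fence removes shade, the
   high fence glint; a low-side-only flag exists. Fewer than four valid
   pixels is a warned no-op. Quartiles use linear interpolation
   (`numpy.percentile` default).
4. **Vector normalization** scales every valid pixel spectrum to unit
   Euclidean norm; zero-norm pixels are masked with a warning.

Masks only ever shrink, and each mask is idempotent: a filter whose
parameters already appear in the provenance log is not re-applied
(recomputing Tukey fences over the survivors would otherwise shrink the
IQR on every pass). Plots whose valid-pixel fraction falls below 0.25
(default) are rejected as a typed outcome. The extraction window is the
full 40 × 40 m grid by default with an optional central 20 × 20 crop;
before any O(n²) distance work the valid pixels are capped at 400 by a
seeded subsample.

## Spectral species

The spectral-species workflow estimates how many clusters a plot's pixels
form, then partitions them:

- **Cluster number**: ten validity indices (Calinski-Harabasz, Hartigan,
  Krzanowski-Lai, silhouette, C-index, Davies-Bouldin, Duda-Hart,
  pseudo-t², Ratkowsky-Lance, Ball-Hall) each propose an optimum over
  k ∈ [2, min(20, n-1)], evaluated on k-medoids partitions of the
  Euclidean distance matrix for coherence with the final clustering step;
  the chosen k is the round-half-up mean of the proposals. The index set
  is configurable. Indices defined for hierarchical splits (Duda-Hart,
  pseudo-t², Hartigan) are applied to the nested sequence of partition
  within-group sums of squares with the classical critical values — the
  standard partition-based adaptation.
  Two short-circuits: near-zero total variance returns k = 1, and if some
  k in range reproduces the pixels exactly (zero within-group variance)
  that k is returned directly — when a partition is exact the cluster
  count is the number of distinct signatures and validity indices are
  undefined (several divide by the within-group dispersion). The second
  rule fires for noise-free pure-pixel renders, never for noisy data.
- **PAM**: classical BUILD + SWAP k-medoids on the same distance matrix,
  fully deterministic with ties broken toward the lowest index; medoids
  always belong to their own cluster, so clusters are nonempty.
- Cluster proportions feed the taxonomic formulas, giving SS richness,
  Shannon, and Simpson.

The ensemble is deliberately conservative (its weakest members are biased
toward few clusters), which matters for the degradation behavior below.

## Phylogenetic-comparative machinery

- **Phylogenetic eigenvectors** are the eigendecomposition of
  `-1/2 J D² J` (D the patristic matrix, J the centering matrix), i.e.
  a principal-coordinates embedding of the phylogeny. The default keeps
  the smallest set explaining 95% of the positive trace, capped at 30.
- **Imputation** is missForest-style: traits with missing cells are
  iteratively regressed on all other traits plus the eigenvectors with
  random forests, visiting columns from least to most missing, stopping
  when the change between successive imputations first increases.
  Observed cells are never modified; out-of-bag R² per trait is returned
  as the imputation-error estimate.
- **Pagel's λ** is estimated by maximum likelihood on [0, 1] under the
  λ-scaled Brownian covariance (off-diagonal shared path lengths times λ),
  with mean and rate profiled out analytically and a profile-likelihood
  interval at 1.92 log-likelihood units. ML replaces a long MCMC run for
  the same estimand — a deliberate desk-scale substitution. The estimator
  is scale-invariant and boundary optima are checked explicitly.
- **BM-vs-OU adequacy**: traits are simulated under BM on the focal tree,
  refit under BM (2 parameters) and single-optimum OU (3 parameters:
  mean, rate, strength α; on an ultrametric tree with a free root the
  root state and optimum are not separately identifiable, so only the
  common mean is counted), and scored with Akaike weights. A replicate
  is "indecisive" when the larger-to-smaller weight ratio is below 2 (the
  class exists in the literature without a printed cutoff; 2 is our
  choice). Optimizer failures are flagged per replicate, never dropped.
- **Trait dendrogram**: Gower distances (range-normalized absolute
  differences averaged over traits observed in both species; zero-range
  traits skipped with a warning) clustered by UPGMA, then all branch
  lengths rescaled by one factor so the root age equals the phylogeny's —
  a time-calibrated stand-in usable wherever a phylogeny is required
  (e.g. trait-dimension PCD).

## Association models

The association between a ground metric y and its analogous spectral
metric x over plots p nested in sites s is

    y_p = α + a_{s[p]} + β x_p + ε_p,  a_s ~ N(0, σ_site²),  ε ~ N(0, σ²)

with priors N(0, 5) on α and β and half-Student-t(3, 0, 2.5) on both
standard deviations. Covariates are not standardized (metrics enter on
their natural scales). Sampling is Gibbs with hierarchical centering
(η_s = α + a_s), which removes the intercept funnel; the half-t priors are
represented by the Huang-Wand inverse-gamma mixture so every conditional
is conjugate. Four chains of 5000 iterations with the first 20% discarded;
convergence requires R̂ < 1.01 and bulk ESS > 1000 (arviz). σ² is floored
at 1e-12 · Var(y) to guard against underflow on degenerate noise-free
data.

The quantile variant replaces the Gaussian likelihood with the asymmetric
Laplace at θ ∈ {0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95}, sampled through
the exponential-normal mixture (latent v_i ~ GIG(1/2, ·, ·), drawn as the
reciprocal of an inverse-Gaussian via the Michael-Schucany-Haas
transform). The ALD scale gets an InverseGamma(0.01, 0.01) prior — the
conjugate family for a parameter that enters both the mixture rate and
the normal variance.

Summaries: evidence ratio `ER = P(β > 0)/P(β ≤ 0)` from the draws
(infinite when all draws are positive); Bayesian R² per draw as
`Var(μ)/(Var(μ) + σ²)`, conditional (μ includes site intercepts) or
marginal; posterior predictive checks with tail probabilities for the
mean, the sd, and the extreme absolute deviation `max|y - ȳ|`. The last
statistic exists because in a location-scale Gaussian the fitted σ absorbs
the sample variance, so the sd discrepancy is matched nearly by
construction and has no power against heavy tails; the extreme deviation
does. Train/test prediction uses random 50/50 splits, posterior-mean
point predictions (unseen sites get a zero intercept), and reports
Pearson ρ, smape `mean(2|ŷ-y|/(|y|+|ŷ|))`, rmsle
`sqrt(mean((ln(1+ŷ)-ln(1+y))²))` (skipped with a warning for negative
values), and the predictive deviation `mean(|ŷ-y|)/max(y)`.

**Pairing registry.** Only mathematically analogous metrics are paired:
Hill-type ground metrics with spectral-species metrics of the same q
order; distance-based ground metrics with MSD/SD/0D(SM). The counted core
is 3 taxonomic, 5 trait, and 6 phylogenetic response models;
z-standardized responses (MTDz, MPDz, PDz) and the higher-q
dispersion ~ 0D(SM) pairs ride along as uncounted extras.

## Community dissimilarity (PCD)

PCD compares two plots through Brownian tip-state variance on the
phylogeny (or the calibrated trait dendrogram): the observed statistic is
the PSV-style mean conditional variance of each community's species given
the other, relative to their unconditional variance, and it is normalized
by a Monte-Carlo expectation under random draws from the pool (2000
seeded replicates per richness by default) so random assemblages expect
1. The compositional factor depends only on shared-species counts
(Sørensen-type), the phylogenetic factor is the ratio, and
`PCD = PCD_comp × PCD_phy` holds by construction. The pool is the union
of species over the analyzed plots. Identical plots score 0; a star
phylogeny collapses PCD to its compositional part. The implementation
follows the covariance formulation of Ives & Helmus (2010), including the
n² denominator convention for single-species communities, and is
cross-checked in the test suite against the picante reference
implementation through Rscript.

## Synthetic landscapes

The generator provides the study conditions: a birth-death phylogeny
(pure-birth by default; the simulator stops at the last speciation, so an
exponential next-event waiting time is appended to every tip branch to
keep between-species distances positive), Brownian traits (with a λ
transform and an OU option), communities of 2–15 species in 20 plots per
site across 10 sites, Dirichlet(1) percent covers scaled to a 60–95%
total, and 40 × 40-pixel cubes on the 384–2512 nm / 5 nm grid (426 bands;
configurable down to ~50 bands for fast tests).

Assembly is a trait-filtering model: species enter a plot with weight
`exp(-φ z²)` where z standardizes the distance of the first trait to a
plot-level optimum (sites carry their own optima, giving the nesting the
multilevel models expect). φ = 0 is neutral; larger φ produces trait
clustering. This generative model is our construction — the framework
itself prescribes none — and exists to realize the clustering /
overdispersion regimes the predictions discuss.

Spectra are a shared green-vegetation template (chlorophyll troughs near
450/680 nm, red edge, NIR plateau, water troughs near 1450/1940 nm) plus
per-trait Gaussian features at seeded centers kept clear of the NDVI
windows, with amplitudes linear in the standardized traits, clipped to
[0, 1]; every pure signature has NDVI > 0.5, and trait distance orders
spectral distance by construction. Pixels mix at most 3 species (weights
proportional to local cover draws), times a lognormal within-species
brightness factor, plus Gaussian sensor noise; a configurable fraction of
pixels carry a low-NDVI soil ramp. All randomness fans out from a single
root seed through named SeedSequence children, so stages are
independently reproducible.

What the generator does *not* emulate: radiative transfer (no PROSAIL
leaf optics), BRDF/topography, phenology, vertical canopy structure,
sub-pixel shade geometry, or spatial autocorrelation of communities.
Passing tests therefore demonstrate internal consistency of the pipeline
and correct behavior under a controlled mixing model, not instrument-level
realism.

## Degradation behavior (a measured caveat)

With sensor noise at zero and pure pixels, spectral-species richness
recovers true plot richness essentially exactly, and the multilevel
slope of S on SS(q0) is ≈ 1 with infinite evidence ratio. As noise rises
the *association strength* (Pearson ρ, marginal R²) decays monotonically,
but the *raw slope* does not: the conservative index ensemble first
compresses the covariate scale (chosen k ≈ 0.8 k_true with sd(x) roughly
halved while ρ is still > 0.9), and because the slope equals ρ·sd(y)/sd(x)
it transiently inflates before collapsing to zero. The degradation tests
therefore check the slope across a no-loss / mostly-destroyed /
fully-destroyed noise ladder (0, 0.12, 0.5 reflectance sd), where it is
monotone, and additionally assert the strictly monotone marginal-R²
decay, which is the scale-free and mechanism-robust form of the property.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with stable statistics: pools of 40–100 species, landscapes of
up to 10 sites × 20 plots, cubes of 16–40 pixels a side with 45–426
bands, 999-replicate SES nulls, 2000-replicate PCD normalizers, 50
replicate datasets for interval coverage, and reduced-draw samplers
(2–4 chains × 1200–1500) wherever a fit is repeated many times; the
single-fit sampler default remains 4 × 5000.
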