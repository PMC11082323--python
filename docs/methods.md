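# Methods

## The model

The evaluation treats the "same" milk trait recorded in two breeds as two
correlated traits. For trait t ∈ {1, 2} (one per breed):

    y_t = X_t β_t + Z_t a_t + e_t

with y_t the lactation records of breed-t cows, X_t a full-rank fixed-effect
design (intercept; farm, calving-year class, calving season and parity,
dummy-coded against a reference level), Z_t the record→animal incidence, a_t
the additive genetic values of **all** animals on trait t, and e_t the
record residuals. The distributional assumptions are

    (a₁, a₂) ~ N(0, G₀ ⊗ H),   e_t ~ N(0, I σ²ₑₜ),   cov(e₁, e₂) = 0.

G₀ is the 2×2 additive (co)variance matrix; its off-diagonal divided by the
geometric mean of the diagonal is the genetic correlation r_g between the
breed-traits. The residual covariance is identically zero because no herd
contains both breeds. Every animal carries breeding values for *both*
traits; the unobserved one is identified only through H and r_g — this is
the channel through which the other breed's reference animals contribute.

H combines pedigree and genomic information. With subscript 2 for genotyped
animals,

    H⁻¹ = A⁻¹ + [0 0; 0 G_blend⁻¹ − A₂₂⁻¹],

where A is the numerator relationship matrix (tabular method; Henderson's
rules with inbreeding-adjusted Mendelian-sampling variances for A⁻¹),
G = MM′ / 2Σpₖ(1−pₖ) is the VanRaden matrix with columns centered by 2pₖ,
and G_blend = (1−w)G + wA₂₂. The explicit four-block H is implemented as
well and the two forms are verified against each other by direct inversion
on randomized instances.

## Estimation

Variance components and breeding values are sampled by a systematic-scan
single-site Gibbs sampler:

* fixed effects and breeding values from univariate normal full
  conditionals (flat priors on β);
* G₀ from an inverted-Wishart with posterior scale S₀ + A_mat H⁻¹ A_matᵀ
  (A_mat the 2×n matrix of current breeding values) and degrees of freedom
  ν₀ + n;
* each σ²ₑₜ from a scaled inverse-χ² over that trait's observed records.

Priors default to weakly informative choices: ν₀ = 4 with the genetic scale
set to 0.3 of each trait's phenotypic variance and the residual scale to
0.5 of it; both fractions and ν are configurable. Posterior summaries use
the retained draws (⌊(chain − burn-in)/thin⌋ samples; 1,800 at the
classical 100,000/10,000/50 settings).

Two numerical choices matter in practice:

* **Monte-Carlo error of posterior means.** Thinned draws remain
  autocorrelated, so Monte-Carlo SEs are estimated by batch means (25
  batches), not by sd/√n. `GibbsConfig.n_location_scans` runs several
  location scans per variance update (default 1); at the 1,000-animal scale
  the variance chain's autocorrelation time drops enough at 5 scans that
  posterior means agree across chain seeds to ±0.01 in h².
* **Oracle equivalence.** With G₀ and σ²ₑ frozen, the sampler's location
  posterior means equal the direct dense solve of the mixed-model
  equations; this is asserted within 3 batch-means SEs per effect (with the
  binomial allowance that a per-effect bound implies across hundreds of
  effects).

Heritability is h² = σ²ₐ/(σ²ₐ+σ²ₑ) per trait. Its headline SE is the
empirical SD of the per-draw h² values; an alternative first-order
propagation form (without the squared-heritability factor and with a single
covariance term) is available as `method="delta_printed"` for comparison
with software that reports that variant. Convergence is checked with the
Geweke z (first 10% vs last 50% of the retained chain, spectral variance at
frequency zero via a Bartlett-kernel long-run variance); |z| > 3 on a
variance component is a warning, not an error.

## Validation protocol

The joint-reference experiment asks how many other-breed animals help the
target breed. Reference sets are nested: the other-breed pool is shuffled
once and prefixes of 0, k, 2k, … animals are appended to the target-breed
base, so successive scenarios differ only by the added animals. The
validation set is the n youngest genotyped target-breed cows born within a
recent window (ties broken by id). Each scenario is run twice — all
phenotypes ("full") and with validation phenotypes masked ("reduced") —
sharing the scenario's H. Reported per scenario, trait and population
(all genotyped target animals vs the validation subset):

    R  = Cor(TBV*, GEBV_reduced),   R²,
    TBV* = b₀ + b₁ GEBV_reduced  (OLS): b₀ = bias, b₁ = inflation.

TBV* is the **full-data GEBV**, a proxy: these quantities measure the
information lost by masking, not accuracy against true merit. b₁ < 1 means
the reduced-run GEBVs are over-dispersed. When a validation animal's
removal empties a fixed-effect level, the level is dropped from the reduced
model with a warning.

## The simulator

The generator emulates the *structure* of a two-breed dairy design, not any
particular dataset:

* **Breeds.** Ancestral allele frequencies uniform on (0.05, 0.95); each
  breed's frequencies drawn from the Balding–Nichols beta distribution at a
  configurable Fst (default 0.1), giving near-zero cross-breed kinship and
  clean PC1 separation.
* **Pedigree.** Disjoint per-breed pedigrees, cohorts of equal size over
  n_generations (default 3), both parents drawn from the previous cohort.
* **Genotypes.** Gene dropping: founder haplotypes site-wise from breed
  frequencies, descendants inherit gametes with Poisson(L) crossovers per
  chromosome (Haldane, no interference). Founder sites are independent, so
  descendant LD is drift LD from the finite founder pool — enough for
  monotone decay curves, but the decay length is set by pool size and
  generations rather than by an ancestral recombination history.
* **Phenotypes.** Each cow gets 1 + Poisson(2.4) lactation records (capped
  at parity 6, ≈3.4 records/cow — the record density of routine milk
  recording, and what makes σ²ₐ/σ²ₑ separable at desk scale). Records sum a
  breed mean, farm/year-class/season/parity effects (drawn once per level),
  the cow's TBV and an independent residual. Breed trait means and SDs
  default to a dual-purpose vs specialist-dairy scale gap (≈4,126 ± 1,406
  vs ≈10,117 ± 2,045 kg). Calving years are grouped into two-year classes;
  ungrouped years would equal birth year + parity exactly and make the
  design singular (the classic year–parity confound).
* **Truth.** SNP effect vectors are shared across breeds with correlation
  r_g and scaled deterministically so the TBV vector is a draw from
  N(0, σ²ₐ G) on the scale of the VanRaden G of the simulated genotypes —
  i.e. stored truth is the same estimand the model fits. Realized values
  (σ²ₐ via the G-metric quadratic form, r_g, Hudson Fst) are recorded.

What the simulator does **not** model: selection, mutation, genotyping
error, permanent-environment effects, sex chromosomes, cross-breed
pedigree links. Passing tests therefore show the estimator recovers the
parameters of this generating process; they do not certify behaviour under
selection or pedigree error.

## Design notes and limitations

* QC runs within each breed before marker intersection; the HWE test is a
  1-df χ² on genotype counts per breed (an exact test is available behind
  `hwe_method="exact"`), at threshold p > 10⁻⁶. Screening bounds are closed
  intervals and fully configurable per breed and trait.
* Allele frequencies for G default to the combined genotyped pool;
  centering makes G's grand sum exactly zero, so with equal breed sizes the
  between-breed block mean equals −(mean within) − trace/(2n²) — the
  "cross-breed kinship ≈ 0" picture requires the realistic unequal design
  (small target breed, large added breed).
* Default blending weight w = 0.05 guards invertibility of G; w = 0 is
  allowed for algebra tests. SNPs monomorphic within a scenario's genotyped
  subset are dropped from G — they contribute zero to both its numerator
  and scale, so this is exact.
* A rank guard (pivoted QR) removes fixed-effect columns that are collinear
  on the observed support, with a warning naming them.
* Identification limits at desk scale: with ~500 cows per breed and ~2,000
  markers the posterior SD of h² is ≈0.03 and of r_g ≈0.15–0.23 (r_g is
  informed only by the small cross-breed block of G). Point estimates from
  a single simulated dataset scatter accordingly; averaging over replicate
  simulations is the way to measure bias.
* Problem sizes used by the shipped checks: the recovery experiment runs at
  500+500 cows / 2,000 SNPs with a 20,000-iteration chain; the acceptance
  script's end-to-end demonstration at 250+250 cows / 1,000 SNPs with
  shorter chains. Unknown-parent groups, REML, marker-effect (SNP-BLUP)
  models and sparse H⁻¹ approximations are out of scope.
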