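# Methods

## The threshold animal model with indirect genetic effects

A dyadic contest produces one binary record per duel. The focal animal's win
(1) or loss (0) is modelled as the sign of a Gaussian liability

l = Xβ + W_D Pe_D + W_C Pe_C + Z_D a_D + Z_C a_C + H_D herd_D + H_C herd_C + e,

where β are fixed effects (year, tournament day, weight category, age- and
weight-difference classes), a_D and a_C are the direct and indirect additive
genetic effects of every pedigree animal, Pe_D/Pe_C the permanent-environment
effects of every animal with contest records, and herd_D/herd_C the effects of
the focal's and the opponent's herd. The random effects are Gaussian with

- cov(a_D, a_C) = G ⊗ A (G the 2×2 genetic block, A the numerator
  relationship matrix),
- 2×2 identity-structured blocks for Pe and herd,
- residual variance fixed at 1.

Fixing σ²_e = 1 identifies the liability scale (probit convention). A logistic
option only rescales the fixed residual to π²/3; the augmentation is always
Gaussian, so "logit" here is a reporting scale, not an exact
logistic-likelihood sampler. The synthetic-data generator can draw genuinely
logistic residuals for robustness exercises.

### Constrained (multimembership) parameterization

The focal/opponent labelling of a duel is arbitrary, so for the *same*
phenotype the direct and indirect variances must be equal and their covariance
negative of the same magnitude — genetic correlation exactly −1. The
constrained model imposes this structurally: a single genetic vector a (and a
single Pe vector) enters through the signed incidence Z_D − Z_C (W_D − W_C),
which is algebraically identical to a_C = −a_D. Consequences, exact per
posterior sample, not asymptotic:

- r(a_D, a_C) = −1;
- total heritability h²_tot = (σ²_aD + σ²_aC + 2σ_aDC)/σ²_P = 0;
- σ²_P = σ²_e = 1 when the herd components are absent.

The unconstrained model leaves all 2×2 blocks free; on data generated under
the constraint its posterior should (and in the test suite does) concentrate
near r = −1 and h²_tot = 0, which is the package's main recovery diagnostic.

### Bivariate threshold–linear model

Dominance (trait 2, threshold) is coupled to one continuous trait (trait 1,
direct effects only; indirect effects on the linear trait are out of scope).
The genetic block becomes 3×3 over (a_1, a_D2, a_C2) with covariance ⊗ A;
Pe and herd blocks are 3×3 where the trait-1 model includes them. The
residual cross-covariance is structurally zero (the traits are never recorded
simultaneously) and σ²_e2 = 1. Trait-1 random-effect shapes:

- `pe_herd` — animal Pe + herd (fertility-like),
- `pe_herd_htd` — adds an iid herd-test-day contemporary group (milk/SCS-like),
- `hyc` — a single herd-year-classifier contemporary group, no Pe/herd
  (morphology-like, single record per animal).

Genetic correlations are computed per posterior sample as
r = σ_a1,aD2 / (σ²_a1 σ²_aD2)^0.5 (and analogously for the other two pairs);
samples whose denominator variance falls below 1e−10 are reported as
undefined (NaN) rather than clamped, because near-zero denominators produce
spurious ±1 spikes.

## Gibbs sampler

Standard data augmentation: liabilities are drawn from truncated normals
(record-specific mean, variance 1, sign fixed by the outcome) using the
inverse-CDF method with clipping at ±38 standard deviations. Location effects
are drawn from the normal full conditionals of the mixed-model equations,
maintaining the residual vector in place. Levels of the genetic and Pe groups
are updated as joint k-vectors across their correlated components — valid
because a focal and opponent can never be the same animal, so the components'
incidences are row-disjoint — which mixes far better than scalar updates when
components are strongly negatively correlated (precisely the regime of the
constrained-truth data). Herd, contemporary-group and fixed effects use
scalar updates, which remain correct when the two herd components share
records (same-herd duels). The sparse A⁻¹ enters the genetic conditionals via
Henderson's rules with inbreeding (Meuwissen–Luo ancestor tracing for F);
correctness is defined against the dense tabular A (tests assert A⁻¹A = I and
agreement with a gene-dropping Monte-Carlo oracle).

Covariance blocks are drawn from their inverse-Wishart full conditionals. The
default prior is flat: the conditional is then the likelihood's own IW kernel
(scale = the effect cross-product matrix S, df = n_levels − k − 1). An
inverse-Wishart prior with identity scale and ν = k + 1 is available as a
knob, but it is *not* weakly informative for components ≪ 1: its prior mode
is ≈ 1/6 per diagonal with infinite mean, and on liability-scale data it
inflated every variance by ~20% and attenuated r(a_D, a_C) from −1 to ≈ −0.88
(the inflation was reproduced independently with an identical model and prior
in JAGS, confirming it is a property of the prior, not of this sampler).
Flat-prior conditionals need n_levels > 2k; fits on miniature data should
pass `prior="invwishart"` or fix the block via `fixed_covariances` (used by
the quadrature-oracle test).

Chain configuration: the production-scale setting is 600,000 iterations,
100,000 burn-in, thinning 100 (5,000 retained samples). The package default
is a 10× reduction (60,000 / 10,000 / 10), and the test suite and acceptance
script use shorter, explicitly stated chains (4,000–10,000 iterations)
matched to their data sizes; at ~20,000 duels the variance-component chains
are stationary well before the burn-in ends (verified by segmenting a 40,000
iteration run). Divergence is policed by a configurable variance cap;
`effective_sample_sizes()` computes per-parameter ESS (arviz) and warns below
200. All randomness flows from one integer seed; identical seeds give
bit-identical chains.

## Summaries

All derived quantities — phenotypic variance, direct/indirect/total
heritability, genetic correlations — are computed per posterior sample and
then summarized, never as ratios of posterior means. Dominance phenotypic
variance is the full decomposition
σ²_P = σ²_aD + σ²_aC + 2σ_aDC + σ²_PeD + σ²_PeC + 2σ_PeDC + σ²_herdD +
σ²_herdC + 2σ_herdDC + σ²_e, with absent components contributing zero. The
HPD95 is the narrowest interval containing at least 95% of samples
(⌊0.95n⌋+1 sorted points; tested against an exhaustive scan and arviz);
an estimate is *significant* when 0 lies outside it. The Monte-Carlo SE of a
posterior mean is sd/√ESS. Unimodality is assumed; a posterior mean outside
its own HPD is flagged. The liability-scale heritabilities are not
transformed to the observed 0/1 scale, and the fixed-effect-variance
adjustment sometimes applied to constrained-model heritabilities is not
implemented; both are documented extension points.

## Genetic trends and the drift null

The trend of a trait is the OLS slope of cohort-mean EBV on birth year,
computed independently for each retained posterior sample of the EBVs;
cohorts below a minimum newborn count (default 100; synthetic runs pass
smaller values) are excluded. The null model of change by drift alone is
pedigree-conditional gene-dropping: breeding values are redrawn through the
*same* pedigree with the estimated additive variance and no selection, each
replicate contributing one slope. The report gives the percentage of
posterior slopes outside the central 95% envelope of the null distribution,
two-sided and both one-sided, plus the full null sample, so alternative
envelope conventions can be applied downstream. Under no selection the
two-sided exceedance calibrates to ~5% (tested); truncation selection on the
direct component drives it to 100% with the indirect component the exact
mirror — in constrained fits slope_D = −slope_C is an algebraic identity.

## Synthetic data

The generator emulates a herdbook-like population: a discrete-generation
pedigree of roughly constant census (defaults: 270 founders, 14 generations,
~3,800 animals — the depth of the motivating herdbook), random mating with
Poisson litter sizes; breeding values gene-dropped with exact
Mendelian-sampling variances d_i·G (d_i from parental inbreeding), so the
stacked vector has covariance G ⊗ A exactly; per-animal Pe triples and
per-herd triples shared between the contest and trait generators, so the
bivariate covariance structure holds across datasets. Contests are drawn
within three weight categories among the youngest ~45% of the pedigree
(mirroring the contestant:pedigree ratio of the motivating population),
with year/day/age-difference/weight-difference classes attached
(effect tables default to zero); outcomes are probit draws on the summed
liability, focal roles are random by construction, and the both-roles filter
is applied so the output satisfies the estimability rule. Default variance
levels: mirror-constrained genetic block with σ²_a = 0.15 and Pe 0.10 on the
liability scale; linear trait standardized to σ²_P = 1 with h² = 0.224
(milk-yield magnitude), Pe 0.15, herd 0.10, HTD 0.10, residual 0.426.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: knockout tournament brackets (pairing is random
within weight category; the models condition on fixed effects, not bracket
structure), winner effects and other carryover, weight dynamics over life,
sire-biased mating and selection-index breeding decisions, heterogeneous
contest residuals, and real fixed-effect magnitudes (defaults are zero).
Recovery results therefore demonstrate correctness of the estimation
machinery under the assumed model, not robustness to these violations.

## Numerical and design choices

- Unknown parents are unrelated, non-inbred base-population members; no
  genetic groups. Pedigrees are topologically sorted (stable Kahn), with hard
  errors naming a cycle member, duplicates, or orphan parents.
- One reference level is dropped per fixed-effect factor except year, which
  keeps all levels and absorbs the liability-scale intercept.
- The dominance herd block is a correlated 2×2 by default and can be dropped
  (`include_herd=False`) — the constrained reference protocol omits herd.
- Truncated-normal draws clip the normal quantile at ±38 to avoid infinities
  at extreme conditional means.
- Degenerate inputs: contests whose both-roles filter empties the data raise
  with advice to re-randomize roles; animals without records still receive
  EBVs through A; trend tests require ≥2 retained cohorts.
- The bivariate model is offered unconstrained only; the near −1 posterior of
  r(a_D2, a_C2) is the internal symmetry diagnostic. When one correlation per
  trait pair is wanted, averaging the two role-specific posteriors is left to
  the caller; the package reports them separately.
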