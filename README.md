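# duelfit

Quantitative genetics of social dominance in dyadic contests.

When two animals fight, the outcome is one phenotype shaped by two genomes:
the focal animal's *direct* genetic effect (a_D) and its opponent's *indirect*
genetic effect (a_C). `duelfit` fits threshold liability animal models to
win/loss records of such duels, estimates the direct, indirect and total
heritability of dominance, couples dominance to continuous production traits
(milk yield, somatic cell score, fertility, morphology) in bivariate
threshold–linear models, and tests whether cohort-level trends in estimated
breeding values exceed what genetic drift alone can produce. It is aimed at
animal breeders and evolutionary quantitative geneticists working with
pedigreed contest data — or anyone who wants a transparent, tested
implementation of indirect-genetic-effect threshold models.

## The model

For duel *k* between focal *i* and opponent *j*, the 0/1 outcome is the sign
of a latent liability

```
l = X b + W_D Pe_D + W_C Pe_C + Z_D a_D + Z_C a_C + H_D herd_D + H_C herd_C + e
```

with `e ~ N(0, 1)` (probit convention), `(a_D, a_C) ~ N(0, G ⊗ A)` where `A`
is the pedigree numerator relationship matrix, and correlated 2×2 blocks for
the permanent-environment (Pe) and herd effects. Everything is estimated by
Gibbs sampling with truncated-normal data augmentation and flat priors on the
covariance blocks.

Because calling one fighter "focal" and the other "opponent" is arbitrary,
the direct and indirect variances of a dyadic trait should be equal and their
covariance its negative — correlation exactly −1. The *constrained*
parameterization (a multimembership model: one genetic vector entering
through `Z_D − Z_C`) enforces this. Under it the total heritability

```
h²_tot = (σ²_aD + σ²_aC + 2σ_aDC) / σ²_P
```

is exactly 0 and the phenotypic liability variance collapses to the unit
residual: selection on winning cannot change the population mean win rate —
a treadmill of competition — yet the individual components stay heritable.

A synthetic-data module generates multi-generation pedigrees, breeding values
with covariance `G ⊗ A`, probit contest outcomes and repeated continuous-trait
records, so every stage is testable without proprietary herdbook data.

## Worked example

```python
import numpy as np
import duelfit as dfit

params = dfit.TrueParameters(herd_cov=np.zeros((3, 3)), n_founders=150,
                             n_generations=8, n_herds=20, n_duels=6000,
                             n_contestants=600)
data = dfit.simulate_study(params, seed=1)           # 1,023 animals, 6,000 duels

model = dfit.DominanceThresholdModel(data.contests, data.pedigree,
                                     constrained=True, include_herd=False)
res = model.fit(iterations=4000, burn_in=1000, thin=4, seed=2)
print(res.summary().round(4))
```

```
                 mean      se  hpd95_low  hpd95_high  significant
quantity
sigma2_a       0.1614  0.0038     0.1057      0.2159         True
sigma2_Pe      0.0747  0.0018     0.0419      0.1026         True
sigma2_e       1.0000  0.0000     1.0000      1.0000         True
...
h2_direct      0.1614  0.0038     0.1057      0.2159         True
h2_indirect    0.1614  0.0038     0.1057      0.2159         True
h2_total       0.0000  0.0000     0.0000      0.0000        False
```

The data were simulated with a true additive variance of 0.15; the constrained
fit recovers it (`sigma2_a` = 0.16, HPD95 [0.106, 0.216]). On the liability
scale with `σ²_P = 1`, `h2_direct` *is* the additive variance. `h2_total` is
identically 0 — the constraint algebra, not an estimate. A drift test of the
direct-component trend on these unselected data,

```python
trend = dfit.ebv_trend(res, "direct", min_cohort=30, n_null_reps=300, seed=3)
print(trend.summary())
```

reports `pct_exceeding_null = 5.7` — about the nominal 5% false-alarm rate of
the 95% drift envelope, as it should be with no selection.

Bivariate fits work the same way through `BivariateThresholdLinearModel`
(trait-1 model shapes: `pe_herd`, `pe_herd_htd`, `hyc`), returning 3×3
genetic/Pe/herd blocks and the cross-trait genetic correlations per posterior
sample.

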