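# Methods

`heatnorm` implements a single-step genomic reaction-norm analysis of heat
tolerance for pig breeding data: weather records and trait-specific critical
periods define an environmental gradient, a Bayesian linear reaction-norm
animal model partitions each animal's merit into an intercept (overall
level) and a slope (environmental sensitivity), and derived genetic
parameters feed a weighted recommendation of the most informative climatic
variable per trait.  Because commercial nucleus-herd data are proprietary,
the package ships a synthetic-data module whose generating model is exactly
the fitted model, so every stage is testable against known truth.

## The model

For record *k* of animal *i*,

```
y_ik = alpha + x_i' beta + omega * phi1_k
       + sum_n ( n0_i * phi0 + n1_i * phi1_k ) + e_ik,
       n in {a, pe, ce},
```

where `x_i` holds the systematic effects (contemporary group = farm x year
x season, parity or age classes, sex where relevant), `omega` is a fixed
regression on the gradient, and each active random effect contributes an
intercept/slope pair: `a` the additive genetic effect, `pe` the sow
permanent-environment effect (shared across a sow's parities), `ce` the
litter (common environment) effect.  Distributions:

```
(a0, a1)  ~ N(0, G0_a  (x) H)      (pe0, pe1) ~ N(0, G0_pe (x) I)
(ce0, ce1)~ N(0, G0_ce (x) I)      e ~ N(0, sigma2_e I)
```

`H` is the single-step relationship matrix combining pedigree and genomic
information; its inverse is built directly as

```
H^-1 = A^-1 + [0 0; 0  tau * (alpha_H G + beta_H A22)^-1 - omega_H * A22^-1]
```

with defaults `tau = omega_H = 1`, `alpha_H = 0.95`, `beta_H = 0.05`.  The
genomic matrix is VanRaden's method 1, `G = ZZ' / (2 sum p_j (1 - p_j))`,
with observed allele frequencies, after marker QC (animal call rate >= 0.90,
SNP call rate >= 0.90, MAF >= 0.01, |observed - expected heterozygosity|
< 0.15; the heterozygosity rule removes deviations *at or above* 0.15 —
removing deviations *below* the cut would invert standard QC intent).
`A^-1` uses Henderson's rules with inbreeding from a Meuwissen–Luo-style
traversal; `A22` comes from the tabular method on the ancestor-restricted
pedigree.

## Gradient and basis

Seven candidate environmental variables (ENVs) are derived per farm-day:
mean/max/min temperature, dew point, relative humidity, Thom's discomfort
index `DI = T - 0.55 (1 - 0.01 RH)(T - 14.5)` (deg C), and the
temperature–humidity index `THI = Tf - (0.55 - 0.0055 RH)(Tf - 58)` with
`Tf` in Fahrenheit.  The exact DI/THI variants in the source literature are
not printed; these standard forms are the package's documented choice and
are swappable.  Each record averages the daily ENV over an inclusive
critical period anchored on event dates ("30 days prior to measurement" is
`[date-30, date-1]`; the event day is excluded, a documented convention).
Windows with under 80% weather coverage are dropped rather than imputed.

The covariate is standardized to `x = 2(v - vmin)/(vmax - vmin) - 1` over
its observed post-QC range and expanded in *normalized* first-order
Legendre polynomials `phi0 = sqrt(1/2)`, `phi1 = sqrt(3/2) x`.  The same
basis is used in the design matrix, in the covariance function
`Gamma_n = Phi G0_n Phi'`, and in the closed-form across-environment
correlation, so all derived quantities are mutually consistent; `G0`
absorbs the normalization, and an unnormalized `(1, x)` convention would
rescale `G0` without changing heritabilities, accuracies or correlations.
The synthetic-data generator applies the identical basis to the true
effects, which makes the configured `G0` matrices the exact estimand.

## Phenotype editing

Per trait: records beyond +-3.5 SD of the mean are removed in a single pass
(n-1 SD; a zero SD removes nothing), then contemporary groups with fewer
than 10 remaining records are dropped (a CG of exactly 10 is kept).

## Sampler

Variance components are estimated by Gibbs sampling on the sparse
mixed-model equations:

* **Locations.** Fixed effects are sampled single-site under flat priors.
  Random-regression effects are sampled in per-level 2x2 blocks; when both
  `a` and `pe` are active, each recorded sow's `(a0, a1, pe0, pe1)` is
  sampled as one 4x4 block.  Blocking matters: the two effects load on the
  same records with identical design columns, and single-site updates mix
  hopelessly along the resulting ridge.  Kernels are numba-compiled and
  maintain the residual vector incrementally.
* **Scales.** Each `G0` block has an inverse-Wishart full conditional with
  scale `U' K^-1 U + S0` and df `q + nu0` (`K` is `H` for `a`, identity
  otherwise); the residual variance a scaled inverse-chi-square.
* **Interweaving.** After the centered updates, each `G0` is re-sampled in
  the non-centered parameterization: the effect is whitened
  (`u_i = L eta_i`), the 2x2 Cholesky scale `L` is drawn from its Gaussian
  conditional given the whitened shapes (a 3-parameter regression), and
  the draw is Metropolis-corrected for the inverse-Wishart prior and the
  `G = LL'` Jacobian.  This ancillarity–sufficiency interweaving step lets
  the variance allocation between `a` and `pe` jump to the data-supported
  value in one move; without it the chain can sit at a collapsed
  (`G0_pe ~ 0`) state for tens of thousands of iterations even though the
  restricted likelihood prefers the truth.

**Priors.** Flat on fixed effects; `G0 ~ IW(df = 4, S0 = 0.1 Var(y) I)` by
default; residual scaled inv-chi-square (df 2, scale 0.01).  A "minimally
informative" tiny fixed scale such as `0.01 I` was evaluated and rejected:
its density grows like `|G0|^-3` toward singular matrices with no
exponential barrier, which actively drags weakly identified blocks into
collapse and breaks parameter recovery.  Scaling `S0` to the trait variance
keeps the prior's weight negligible (a few df against thousands of levels)
while suppressing the singular ridge.  Both choices are config-overridable.

**Chains.** Desk-scale default 5,000 iterations, burn-in 2,000, thin 10.
The study-scale preset `full` (600,000 / 300,000 / 60; `full-ibf`
900,000 / 600,000 / 60) reproduces the original analysis settings.
Records are sorted canonically (animal, record id) before assembly so a
fixed seed reproduces chains bit-for-bit.  Convergence is reported via
Geweke z-scores (first 10% vs last 50%, ESS-based standard errors capped at
the segment length) and effective sample sizes; |z| > 2 or ESS < 100 is
flagged.  This replaces the Raftery–Lewis diagnostic of the original
workflow.

**BLUP mode.** With variances fixed and the noise term switched off, the
same sweeps perform Gauss–Seidel iteration whose fixed point is the direct
sparse MME solution; this is how the "posterior means match a direct
solve to 1e-3" consistency check is run, since the Monte-Carlo error of a
genuinely sampled chain exceeds that tolerance at any practical length.

## Derived parameters

* Heritability at gradient point *k*:
  `h2_k = Gamma_a,kk / (sum_n Gamma_n,kk + sigma2_e)`; inactive effects
  contribute zero.
* GEBV accuracy: `Acc_it = sqrt(1 - PSD_it^2 / ((1 + F_i) sigma2_a,t))`
  per animal and term (intercept/slope), with the same-chain posterior-mean
  additive variance per term; negative reliabilities from sampling noise
  are clipped to 0 and counted.
* Across-environment genetic correlations `r_kk'` from the closed-form
  expansion (equal to `Gamma_a,kk'/sqrt(Gamma_a,kk Gamma_a,k'k')`), on the
  10th–90th percentile window of the covariate; G x E is classed large
  (r < 0.50), moderate (0.50 <= r <= 0.80) or weak (r > 0.80), applied to
  the trimmed-grid mean (minimum also reported).
* Sire reaction norms for sires with >= 30 offspring; the five highest and
  five lowest slopes are the heat-tolerant / heat-susceptible extremes.
* Between-trait correlations: reliability-weighted Pearson correlations of
  GEBVs over animals with all four accuracies >= 0.30, weights
  `w_i = sqrt(Rel_x Rel_y)` (the printed weight expression simplifies
  algebraically to this), `SE = sqrt((1 - r^2)/(n - 2))` (the conventional
  square-root form; the source prints the formula without the root).
  Spearman rank correlations are also provided.

## Environmental-variable selection

Each candidate "ENV x critical period" fit is scored on (1) the slope
additive variance, (2) the mean slope-GEBV accuracy, (3) the mean
across-animal SD of GEBV at the 0/25/50/75/100th percentile gradient
points.  Criteria are min–max normalized within the comparison set (rank
normalization available), weighted 0.5/0.3/0.2, and summed; ties break by
criterion 1, then ENV name.  Scoring is done within each critical period,
with the joint table available for a cross-period reading.

## Synthetic data: what it does and does not emulate

The generator produces a multi-generation pedigree with litters and
repeated sow records, gene-dropped SNP genotypes (founders in
Hardy–Weinberg proportions, Mendelian inheritance, no linkage
disequilibrium), farm-linked sinusoidal weather with independent humidity
cycles (dew point via the Magnus formula), and phenotypes from the exact
reaction-norm model above.  Defaults describe a litter-size-like trait
(mean 13, residual SD 1, intercept heritability ~0.1) with clearly present
G x E.  Not modelled: LD structure (irrelevant for a relationship
estimator), selection, genotyping error, missing weather, within-barn
microclimate.  A green recovery test therefore establishes that the
estimation machinery is correct under the stated model, not that the model
describes any particular real herd.

Two recording designs exist.  The default records one phenotype per
pedigree litter (only dams of retained litters are recorded).  The
`record_all_females` design gives every female `records_per_sow` parity
records, litters of non-retained sows being phenotyped without their
piglets entering the pedigree.  Recovery studies use the latter: separating
`sigma2_a0` from `sigma2_pe0` rests entirely on recorded relative pairs,
and with only two recorded generations of dams the restricted likelihood
along the exchange ridge is nearly flat (profiled directly during
development), making the split genuinely unidentifiable rather than merely
slow to sample.

For driving-ENV recovery studies the seven candidate covariates are drawn
from an equicorrelated Gaussian copula with uniform marginals (pairwise
latent r = 0.65, within the realistic |r| <= 0.8 regime) rather than from
the weather pipeline: THI, DI and mean temperature are deterministic
functions of the same daily series, so window averages of the seven
weather-derived ENVs correlate above 0.95 and no generator faithful to
that arithmetic could make the driver identifiable.  The uniform marginal
matters too — seasonal window averages sweep their observed range, and a
thin-tailed marginal would concentrate the standardized gradient near its
midpoint and starve the slope of information.  The weather ->
window-average path is validated separately.

## Numerical choices and edge cases

* Standardization range from observed post-QC covariates; a constant
  covariate is a hard error (gradient undefined).
* `H^-1` blends `alpha_H G + beta_H A22` (the sum form); with no genotyped
  animals it reduces to `A^-1` exactly.
* Mean imputation (2p) of missing genotypes surviving QC contributes zero
  to centred marker scores.
* Full-conditional scale matrices are Cholesky-checked; a non-PD scale
  aborts with the iteration index.
* `h2` requires a positive phenotypic variance at every grid point;
  accuracies require positive additive variances.
* Tie-breaks and band boundaries are documented above and fixed, so
  recommendations are permutation-invariant across candidate input order.

## Known limitations

Single-trait Gaussian models only (count traits are treated as Gaussian);
heterogeneous residual variance along the gradient is not modelled;
between-trait correlations are GEBV-level approximations, not multi-trait
posterior correlations; desk-scale dense `A22`/`G` limit the genotyped set
to a few thousand animals; the chain presets trade Monte-Carlo error
against runtime and the desk preset is not a substitute for the full
setting on weakly identified datasets.
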