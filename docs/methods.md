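# Methods

## The trait model

An animal's performance is modelled as a linear reaction norm on the level
of environmental challenge `X`:

    y_jk = mu0 + A0_j + E0_jk + X_jk * (muR + AR_j + ER_jk)

`A0` (production potential) is the genetic intercept — performance under
ideal, zero-challenge conditions; `AR` (resilience) is the genetic slope —
the change in performance per unit of challenge, negative on average because
challenge depresses performance.  `(A0, AR)` are jointly normal with
variances `var_a0`, `var_ar` and correlation `rho_a`; the per-record
residual intercept and slope deviations `E0`, `ER` are independent normals,
so the residual variance of a record at challenge `x` is
`var_e0 + x^2 * var_er` with no residual covariance term.  Heritability at
challenge `x` is

    h^2(x) = (va0 + x^2 var + 2x cov) / (va0 + x^2 var + 2x cov + ve0 + x^2 ver)

(the final denominator term uses the residual *slope* variance; a flag
reproduces the alternative form in which it does not enter, which we regard
as a typographical variant since the slope residual would otherwise never
affect any quantity).

Default parameters: `mu0 = 10`, `muR = -3`, `var_a0 = var_ar = 0.1`,
`var_e0 = var_er = 0.9`, `rho_a = -0.5`, so both traits have heritability
0.1 and the mean performance drop across the full challenge range `[0, 2]`
is 6 phenotypic standard deviations at zero challenge.

## Genome simulation

Founder genomes are produced by a forward mutation-drift simulation: a
population of constant size (100 diploids, half per sex, at full scale)
evolves for 10,000 generations over 26 chromosomes of 1 Morgan carrying
200,000 equidistant biallelic loci with recurrent symmetric flip mutation at
1e-5 per locus and generation.  Recombination is Haldane: Poisson crossover
counts with uniform positions and no interference.  After burn-in the
population expands exponentially to 10,000 individuals over 5 generations;
only segregating loci are retained.  At full scale this yields on the order
of 4,800 segregating SNPs per chromosome; the full simulation takes hours
and is never run by the test suite.

Base populations are drawn from the expanded pool without replacement
within a chromosome and independently across chromosomes, so replicates
sharing a pool are effectively independent.  Gene dropping through
pedigrees is pure Mendelian inheritance with the same recombination model
and no new mutation.

A `desk` genome configuration (3 chromosomes, 8,000 loci, N = 50, 400
burn-in generations) keeps the scaled mutation pressure `4*N*mu` of the full
genome times a factor of two; the boost is needed because a 3-chromosome
genome otherwise leaves too few segregating loci to select 450 top-MAF loci
per chromosome for the desk QTL/SNP panels.  Desk genomes simulate in
seconds and carry all property tests; they are never used to claim
full-scale numbers.

## Genetic architecture

Per chromosome, the 1,500 segregating loci (450 at desk scale) with the
highest minor allele frequency in the base generation are split at random
into 500 pleiotropic QTL and 1,000 SNP-panel loci (150/300 at desk scale);
MAF ties break by locus index so the choice is reproducible.  QTL effects on
(A0, AR) are drawn from a standard bivariate normal with correlation
`rho_a`, then each trait's effects are rescaled so the *empirical* variance
of true breeding values in the base generation equals the target exactly
(the correlation is then only approximate, converging with QTL count).
TBVs are dosage-weighted effect sums, centred on the base mean — the
population mean is carried by `mu0`/`muR`.

## Environment and phenotyping

Animals are phenotyped in flocks: contemporary groups with mean challenge
drawn uniformly on the overall range shrunk by half a flock width
(`Xmax * epsilon / 2`) at each end; each record's challenge is uniform
within the flock interval, so all records stay inside the overall range.
Allocation schemes: RND (individual-level uniform), CLS (one flock per
paternal half-sib family), AST (sires ranked by true A0 descending paired
with flocks ranked by mean challenge ascending, in contiguous rank blocks
when families outnumber flocks) and DIS (AST reversed).  Founders have no
sire family and are allocated uniformly under every scheme; for the
allocation-contrast studies only the family-structured generation is
phenotyped, because randomly allocated founder records dilute the clustering
contrast (the default configuration still phenotypes both parental
generations, and the choice is a config switch).

## Evaluation

Variance components of the bivariate random-regression model are estimated
by average-information REML on the dense phenotypic covariance

    V_ij = K[a_i, a_j] * (va0 + cov (x_i + x_j) + var x_i x_j)
           + delta_ij (ve0 + ver x_i^2)

where `K` is the pedigree NRM (tabular method) for BLUP or the VanRaden
method-1 GRM (observed allele frequencies of the genotyped set, 0.01 added
to the diagonal before use) for GBLUP.  The optimizer works on an
unconstrained scale — log-Cholesky factor of the 2x2 genetic covariance and
log residual variances — so estimates are feasible by construction; each
AI-Newton step is halved until the restricted likelihood strictly improves,
and a quasi-Newton (L-BFGS-B) polish with the analytic gradient finishes
fits where the AI direction stops being an ascent direction (typically near
the `|rho| = 1` boundary).  Convergence requires |delta logL| < 1e-6 and
max parameter change < 1e-6 on the unconstrained scale within 200
iterations.  A fit is *infeasible* when it fails to converge, pins any
variance below 1e-8 of the phenotypic variance, or implies |genetic
correlation| > 1 - 1e-8; infeasible replicates are excluded from accuracy
and bias averages and counted in the failure rate.  Standard errors come
from the inverse AI matrix at the solution.  With fewer than two distinct
challenge values the slope is unidentifiable and the fit degrades to the
univariate animal model.

Breeding values are the exact BLUP `u_hat = Cov(u, y) P y`, identical to
Henderson's mixed-model equations with per-record weights
`1 / (ve0 + ver x^2)`; animals without records are predicted through `K`.
Fixed effects are `(mu0, muR)` estimated jointly by GLS.

When the challenge is unknown, a two-step procedure is used: first the
conventional model `y = mu + F_l + a_j + e` with *fixed* flock effects and a
single additive effect (univariate REML + BLUP); then the estimated flock
effects are mapped affinely onto `[0, Xmax]` with the best-performing flock
at zero challenge and the worst at `Xmax`, and the reaction-norm model is
fitted with that proxy as the covariate.  Flock-effect estimation error and
the loss of within-flock heterogeneity arise naturally from the
composition.  The rescaling happens within each analysis, using that data
set's best and worst flocks.

## Metrics

Accuracy is the Pearson correlation between (G)EBV and TBV on the assessed
cohort (the unphenotyped final generation of the random-selection design).
Standardized dispersion bias is computed from the TBV-on-EBV regression
slope `b` as `1/b - 1` for `b < 1` and `1 - b` for `b >= 1`: zero iff the
EBVs have the right dispersion, positive when over-dispersed
(over-estimated), symmetric in magnitude under `b <-> 1/b`.  The printed
two-branch form that is non-positive in both branches is available behind a
flag; we treat it as sign-inconsistent with its own verbal definition.
Replicate aggregation reports converged-only means with normal 95% CIs and
a failure rate over all replicates.

## Study designs

*Random-selection design* (prediction quality): three non-overlapping
generations with half-sib structure — 100 males + 1,100 females; each male
by 11 dams, one offspring each (1 male, 10 females per family); each
second-generation male by 10 second-generation dams, giving 1,000 final
animals that carry no phenotypes and whose (G)EBVs are assessed.  Desk
variant: one-tenth cohorts (the ordering studies use 15 males + 165
females).

*Selection design* (response): discrete generations of 8,100 (2,700 males,
5,400 females); a tenth of males and half of females are selected on
`I = (1 - alpha) A0_hat + alpha AR_hat` from a two-step genomic evaluation
(or on conventional-model EBVs), mated at random 10 females per male with
litters of 3 (1 male, 2 females).  The generation-0 parent set is 270 males
+ 2,700 females sampled from the pool.  Evaluation uses the current
cohort's records and GRM only (a config flag can cumulate).  Flock means,
allocation and residuals are redrawn every generation.  The trajectory reports
cohort TBV means and variances on the trait scale; "gain after n
generations" is the change in cohort mean TBV from the first cohort to the
unselected offspring of the last selection round.

## Desk-scale study conditions used by tests and the acceptance script

The test suite and `scripts/acceptance.py` run everything at desk scale on
one CPU in minutes: desk genome as above; ordering studies with 15 + 165
base animals, 10 flocks, 10–20 replicates; selection studies with cohorts
of 270 (9 males + 90 females selected), 5 generations, 2 replicates.
Desk-scale accuracies (~0.2–0.3 for production potential with GBLUP and 3
records) sit well below the full-scale values (~0.4) because one-tenth the
animals and a 3-chromosome genome carry far less information; the *ordering*
claims (more records better; GBLUP over BLUP; random allocation best for
production-potential accuracy; two-step accuracy falling with flock
heterogeneity; the monotone index trade-off; the conventional model's
range-dependent resilience response) are scale-stable and are what the
acceptance battery asserts.  Passing desk tests therefore demonstrates the
mechanics and the qualitative structure, not the full-scale magnitudes.

## Numerical choices and degenerate inputs

- GRM stabilization: +0.01 on the diagonal before use (configurable);
  guards near-singular GRMs from clone-like full sibs.
- REML starting values: an OLS fit of `y ~ 1 + x` supplies the residual
  variance, split 50/50 between genetic and residual at the intercept scale
  and (scaled by `mean(x^2)`) at the slope scale; zero starting covariance.
- Monomorphic SNP panels, empty shrunken flock intervals, pedigrees listing
  children before parents, all-equal flock effects, and zero-variance EBV
  vectors raise `ValueError` with specific messages.
- Ties: MAF ties break by locus index; truncation-selection ties keep the
  earlier candidate (stable sort).
- All randomness flows from `numpy` `SeedSequence` spawning, one root seed
  per run; chromosome simulations, replicates and pipeline stages use
  independent child streams, so every output is reproducible bit-for-bit
  from (config, seed).

## What the synthetic data does not emulate

Real sheep LD profiles (the mutation rate targets a segregating-SNP count,
not an empirical LD curve), sex chromosomes, crossover interference,
variable recombination maps, overlapping generations, non-linear reaction
norms, exponential heteroscedastic residual models, residual
intercept-slope covariance, and longitudinal resilience indicators.
Results on real data would additionally face genotyping error and
incomplete pedigrees, neither of which is simulated.

## Known limitations

- The dense-V REML scales cubically with record count; it is exact and
  transparent but full-scale scenarios (tens of thousands of records) take
  hours per replicate on one CPU.
- At desk scale the REML estimates are noisy and a visible fraction of
  replicates ends infeasible (as at full scale with one record per animal);
  ordering tests therefore average 10–20 replicates and the dispersion-bias
  contrast uses replicate medians.
- The narrow-range selection scenarios rescale the challenge proxy onto
  `[0, Xmax]` even though the true range is half as wide; the implied
  affine distortion is part of the procedure being studied, not corrected
  away.
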