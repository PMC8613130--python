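# Methods

## Problem and model

`smcimpute` treats missing values in the explanatory variables of two-level
(multilevel) analyses whose substantive model is *nonlinear in the
covariates*: random slopes, cross-level interactions, cluster-mean
centering, polynomial terms.  The canonical substantive model is, for unit
*i* in cluster *j*,

    y_ij = beta0 + beta1 (x_ij - xbar_j) + beta2 xbar_j + beta3 z_j
         + beta4 (x_ij - xbar_j) z_j + beta5 xbar_j z_j
         + u_0j + u_1j (x_ij - xbar_j) + e_ij,

with (u_0j, u_1j) ~ N(0, T), e_ij ~ N(0, sigma^2).  Conventional
multivariate-normal or reversed-conditional imputation models cannot
represent the conditional distribution of an incomplete x under such a
model; the resulting estimates of interaction coefficients and slope
variances are biased.

The engine instead factorizes the joint distribution of all analysis
variables into an ordered *sequence* of conditional univariate models —
one per explanatory variable, each conditioning only on variables placed
earlier — closed by the substantive outcome model itself:

    g(y, x) = g_y(y | x) * prod_p g_{x_p}(x_p | x_1 .. x_{p-1}).

Because the substantive model is part of the factorization, imputations
are by construction compatible with the intended analysis
(substantive-model-compatible, sequential-modeling flavour).

## Sampler

Each conditional model is either a normal linear mixed model (level-1
variables; random effects carried explicitly by data augmentation) or a
normal regression at the cluster level (level-2 variables).  One MCMC
iteration:

1. **Gibbs sweep** — every model's parameters are redrawn from their exact
   full conditionals given the current completed data: fixed coefficients
   (multivariate normal, flat prior), cluster random effects u_j
   (multivariate normal), residual variances (inverse gamma(1e-3, 1e-3)),
   random-effect covariance T (inverse Wishart, df = dim+1, scale 1e-3 I).
   All priors are weakly-informative conjugate defaults and are exposed in
   the configuration.
2. **Metropolis-Hastings sweep** — for every incomplete variable q,
   proposals are drawn for the missing cells and accepted on the
   posterior-density ratio: the log ratio sums the log densities of q's
   own conditional model and of every later model in which q appears as a
   predictor (including through derived terms), with cluster means,
   deviations, interactions and powers recomputed under the proposal.

   *Acceptance granularity.*  When q reaches any relevant model through an
   aggregated score (a manifest cluster mean or within-deviation, or a
   cluster-level model), all missing cells of a cluster are proposed and
   accepted **jointly**: changing one cell moves the cluster mean and
   hence the posterior of every other cell.  When every relevant model
   references q only through row-local terms (identity, powers,
   interactions with other variables), the density factorizes by row and
   each cell is accepted **individually**.  Per-cell acceptance is what
   lets the chain move between the two branches of the bimodal
   conditional that a quadratic outcome term creates (two x values
   explain the same y); joint whole-cluster proposals cannot flip one
   cell between branches and would freeze the chain on whichever branch
   it started.

   *Proposal mixture.*  Each sweep uses, with probability 0.5, per-cell
   Gaussian random-walk steps with adapted scales, and otherwise an
   independence proposal drawn from q's own conditional model (whose
   density then cancels out of the acceptance ratio, leaving the
   likelihood ratio of the later models).  Both kernels preserve the
   target; the mixture combines local exploration with position-
   independent jumps.

Cluster means are *manifest* — recomputed from the current completed
values — matching the term algebra used at analysis time.  Observed cells
are never touched; a fingerprint of the observed data is asserted constant
across the run.

**Initialization.**  Missing cells start from draws out of the
complete-case linear regression of the variable on all fully observed
variables — importantly including the outcome.  A start that ignores y
(e.g. mean/SD draws) can place whole clusters on the wrong branch of the
bimodal posterior that arises under quadratic terms, a basin the sampler
then takes impractically long to leave; conditioning the start on y puts
cells on the correct branch.  Initialization affects mixing only, never
the stationary distribution.  A `moments` fallback (observed-cell mean/SD
draws) is used when no complete covariates exist.

**Proposal adaptation.** Each (variable, cluster) pair carries its own
proposal SD, initialized at half the observed SD of the variable.  During
burn-in, every 25 iterations the SD is multiplied by
exp(rate - 0.45) whenever the windowed acceptance rate leaves the
[0.30, 0.60] band.  Scales freeze at the end of burn-in, so the post
burn-in chain is a valid fixed-kernel MH sampler.  Any fixed kernel after
burn-in preserves the stationary distribution; the adaptation scheme only
affects mixing speed.

**Controls.** Engine defaults: burn_in = 2000, n_between = 100 iterations
between saved datasets, m = 10 imputations.  The simulation harness and
the packaged acceptance studies use burn_in = 400-500 and n_between =
30-50: on the small conditional models of the study designs the chain
reaches its stationary regime within a few hundred iterations (pooled
estimates at burn-in 500 and 2000 agree to three decimals in spot checks),
and the shorter spacing trades a little between-imputation correlation for
a large reduction in compute.  These sizes are stated here as the
package's own reduced-scale choice.

**Diagnostics.** Acceptance rates per variable and a split-chain potential
scale reduction (R-hat) per parameter, computed from the halves of the
post-burn-in chain of the single run (the standalone `rhat()` accepts >= 2
independently seeded chains).  The statistic is clipped below at 1.0.
Values above 1.1 are logged as potential non-convergence; non-convergence
is reported, never fatal.

## Analysis and pooling

`fit_lmm` estimates the substantive mixed model by maximum likelihood with
a profiled solver: writing Lambda = T/sigma^2, beta and sigma^2 have
closed-form GLS/profile solutions via the Woodbury identity, leaving only
the Cholesky factor of Lambda (1-3 numbers) to a Nelder-Mead search.  The
fit agrees with statsmodels MixedLM (ML) to optimizer precision and is
roughly two orders of magnitude faster at simulation sizes, which is what
makes the replication studies feasible on one CPU.  Rows with any missing
model variable are dropped first, so the same function is the
listwise-deletion comparator.  Singular fits set `converged=False` rather
than raising.

Rubin's rules pool per-imputation estimates: Qbar = mean, B =
between-imputation variance, Ubar = mean sampling variance, total T = Ubar
+ (1 + 1/m) B, degrees of freedom by the 1987 formula with the
Barnard-Rubin small-sample adjustment, 95% intervals on the t scale.  The
complete-data df entering the adjustment is (number of clusters - number
of fixed effects) — conservative for cluster-level quantities, and
configurable.  Non-converged fits are dropped with a logged count; more
than 20% dropped flags the pooled result.  Variance components are
averaged across imputations as point summaries (no SEs).

## Synthetic-data generators

Three study designs generate standardized variables
(Var(x) = Var(y) = Var(z) = 1, zero means):

* **Study 1** (conflated effects): x = x_L2 + x_L1 with Var(x_L2) =
  rho_Ix; (x_L2, z) bivariate normal scaled so Cor(x, z) = rho_xz = .20;
  outcome y ~ x + z + x:z with random intercept and a random slope on x
  (tau1^2 = .10, tau01 = 0); coefficients (.40, .20, .20).
* **Study 2** (centered effects): same covariates; outcome uses manifest
  cluster-mean centering, y ~ wdev(x) + cmean(x) + z + wdev(x):z +
  cmean(x):z with a random slope on wdev(x); coefficients
  (.40, 0, .20, .20, 0).
* **Study 3** (nonlinear covariate relation): z standard normal;
  x_L2 = phi0 + phi1 z + phi2 z^2 + eps with phi1 = sqrt((1-w) R2),
  phi2 = sqrt(w R2 / 2), phi0 = -phi2, Var(eps) = rho_Ix (1 - R2), and
  x_L1 ~ N(0, (1-rho_Ix)(1-R2)); total R2 = .50.  The variance of x not
  explained by z, (1 - R2), is split between the levels by rho_Ix, so
  Var(x) = 1 exactly and Cor(x, z) = sqrt((1-w) R2): about .71 at w = 0,
  0 at w = 1.  The outcome adds quadratic terms, y ~ x + z + x:z + x^2 +
  z^2 (all coefficients .15) with a random slope on x.

**Outcome calibration.** tau1^2 is fixed; tau0^2 and sigma^2 are solved so
that the intraclass correlation of y equals rho_Iy and Var(y) = 1.  The
fixed-part between/within contributions are integrated exactly by
Gauss-Hermite quadrature (all integrands are low-degree polynomials in
jointly normal variables), including the finite-n corrections of manifest
centering in study 2 (deviation variance s^2(1 - 1/n); sample-mean noise
s^2/n).  The intercept beta0 is set so E[y] = 0 exactly — interaction and
quadratic terms have nonzero means even with centered inputs.  An
infeasible rho_Iy (given tau1^2 and the coefficients) raises an error
stating the feasible range.

In study 3 the correlation-pinned covariate construction gives the level-2
part of x a variance of R2 + rho_Ix(1 - R2) (= .60 at the defaults), so
the fixed between-cluster share of y alone exceeds a nominal ICC of .20:
the printed design is internally inconsistent.  The study-3 factory
therefore clamps rho_Iy to the smallest feasible value plus 0.02 (keeping
Var(y) = 1 exact, which pins the missingness calibration and the effect
scales); the estimands are unchanged.

**Missingness.** A latent propensity r = lambda0 + lambda1 y + v with
v ~ N(0, 1 - lambda1^2) deletes a cell of the target variable where
r > 0.  With Var(y) = 1 and E[y] = 0, r has unit variance, so lambda0 is
the standard-normal quantile of the target proportion (-0.674 for 25%,
-0.524 for 30%) under MCAR and MAR alike; lambda1 = 0 is MCAR, .35/.70
are MAR of increasing strength.  Under MAR in study 3 the realized
proportion deviates slightly (~26% rather than 30%) because y is
non-normal there; this is a property of the propensity mechanism itself,
not of the calibration.

**What the generators do not emulate:** unbalanced cluster sizes,
non-normal residuals, categorical covariates, missingness in more than one
variable, and MNAR mechanisms.  Passing tests therefore speak to the
correctness of the sampler and pooling under the stated designs, not to
robustness against those features of real data.

## Reduced problem sizes

The replication harness runs the original designs at reduced scale, chosen
once as a desk-scale compromise:

* study-3 bias under MAR (lambda1 = .70): J = 250, n = 20, 30 replications
  per nonlinear weight w in {.25, .50, .75, 1}, m = 10;
* study-1 coverage under MCAR: J = 100, n = 10, ICC .20, 200 replications,
  m = 10;
* calibration checks: 10^6 draws (missingness), 4x10^5 level-2 units
  (covariate correlation).

Monte Carlo SEs are reported next to every bias/RMSE/coverage figure; the
bias checks allow two MC SEs of slack.

## Numerical choices and edge cases

* All randomness flows from `numpy.random.Generator`; replications use
  `SeedSequence.spawn` substreams, so every study is reproducible from one
  base seed and runs are bit-identical given seed and config.
* Degenerate clusters (n_j = 1) are allowed; the u_j conditional stays
  proper through the prior.
* A duplicated term yields a duplicated design column (declaration-order
  contract, no deduplication); the resulting singular fit is reported via
  the convergence flag.
* Level-2 variables are stored per row and validated for within-cluster
  constancy (and all-or-none within-cluster missingness) at load time;
  violations are errors.
* Proposals are drawn only for missing cells; observed cells in the same
  cluster are never perturbed.
* With no missing cells the engine degrades to pure Bayesian estimation of
  the sequence and returns m identical copies of the input.
* Default sequence ordering (`order: auto`): level-2 variables before
  level-1, then ascending percentage of missing data — conditional models
  for the easier, more complete variables first.

## Known limitations

* Only normal conditional models: no binary/ordinal covariates, no
  heteroscedastic level-1 variances.
* Two-level hierarchies only; no three-level or cross-classified designs.
* Latent (measurement-error-corrected) cluster means are not implemented;
  manifest means can differ from latent ones in strongly unbalanced
  designs.
* The slope variance shows the expected small-sample downward bias at
  n = 10 with the short chains used in the harness (about -8% in the
  packaged coverage study), consistent with the behaviour of this model
  class; regression coefficients are unaffected.
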