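# Methods

`ecoglmm` implements a complete analysis workflow for ecological count data
with repeated measures — acoustic bat monitoring, camera traps, point
counts — where the observational unit is a *site-night* (one detector-night
at one monitoring site) and interest centres on how site- and night-level
covariates shift expected activity per taxon.

## Model

For each taxon, counts follow a log-link generalized linear mixed model
with a site random intercept:

    y_ij ~ F(mu_ij, dispersion),    log mu_ij = x_ij' beta + b_i,
    b_i ~ Normal(0, sigma_b^2),

where `i` indexes sites and `j` site-nights within a site. Three error
families `F` are supported, distinguished by their mean-variance
relationship:

| family    | variance            | dispersion | parameterization |
|-----------|---------------------|------------|------------------|
| `poisson` | mu                  | —          | —                |
| `nbinom1` | phi * mu            | phi > 1    | Gamma-Poisson with shape mu/(phi-1), success prob 1/phi |
| `nbinom2` | mu + mu^2 / theta   | theta > 0  | Gamma-Poisson with shape theta |

NB1 ("quasi-Poisson shape") and NB2 are both negative binomials; they
differ in whether overdispersion grows linearly or quadratically with the
mean. Dispersion parameters are estimated on unconstrained scales
(log(phi - 1), log theta) so the optimizer never needs bound handling for
them in practice.

An optional zero-inflation submodel mixes a structural zero into the count
distribution with per-observation probability `pi_ij`,
`logit(pi_ij) = z_ij' gamma`:

    P(y = 0) = pi + (1 - pi) F(0 | mu),   P(y = k) = (1 - pi) F(k | mu).

The ZI component carries no random effect; if the grouping factor appears
in the ZI formula it enters as fixed effects (one parameter per site —
expect parameter proliferation, and a warning-sized grain of salt, when
sites are many). Because a ZI submodel is weakly identified when zeros are
rare, fitting refuses ZI specifications when fewer than 5% of observations
are zeros unless explicitly overridden.

## Estimation

The marginal likelihood integrates the random intercept out per site.  The
integral is computed by *adaptive Gauss-Hermite quadrature*: for each site
the conditional mode of b is found by a damped Newton iteration on the
joint log-density (analytic first/second derivatives for every family; the
zero-inflation mixture reweights the y = 0 scores by the share of P(y=0)
attributable to the count process), then 7 nodes (default) are placed
around the mode scaled by the local curvature. One node is exactly the
Laplace approximation; `n_nodes` is exposed on `fit()`.

Optimization is L-BFGS-B over (beta, gamma, unconstrained dispersion,
log sigma_b) with an analytic gradient: for sigma_b = 0 the score is exact;
with a random intercept it is the posterior-weighted score over the current
quadrature nodes (node positions treated as fixed). With 5+ nodes this
matches the numeric gradient of the quadrature objective to ~1e-4 and is an
order of magnitude cheaper; with fewer nodes the fixed-node bias is
material, so Laplace-mode fits (`n_nodes < 5`) fall back to
central-difference numeric gradients. A finite-difference Newton polish
runs after L-BFGS-B (Hessian built from score differences, reused across
steps) and drives the gradient max-norm to ~1e-9; this is what makes the
sigma_b = 0 path reproduce ordinary GLM maximum-likelihood estimates to
better than 1e-8, and makes raw-fit vs scale2-fit effect estimates agree to
optimizer precision.

Wald standard errors come from the inverse observed information
(central-difference Hessian of the score). When that matrix is not positive
definite the SEs are reported as missing, never fabricated. `log sigma_b`
is box-bounded to [-8, 5]; a fit at the lower bound is effectively
sigma_b = 0. Fitting is fully deterministic given the data — no randomness
enters the estimation path.

Known limitation: maximum likelihood (this package deliberately implements
no REML) shrinks the between-site SD when many site-level fixed effects are
estimated from few sites. At a 36-site design with ~8 site-level
regressors, the first-order deflation of sigma_b_hat is
sqrt((36-8)/36) ~ 0.88, and simulation shows the realized shrinkage is
somewhat larger. This is a property of ML shared by the standard mixed-model
engines (verified against glmmTMB on identical data, which agrees with this
fitter to ~1e-3 on all parameters); fixed-effect estimates are unaffected.
Treat reported sigma_b as a conditional-fit quantity, not an unbiased
estimate of the population between-site SD.

## Standardization and effect sizes

Continuous predictors are standardized by **two** sample standard
deviations, `(x - mean) / (2 sd)` (sample SD, n-1 denominator), which puts
them on the same footing as binary 0/1 covariates (a balanced binary
variable has SD 0.5). Each predictor's raw mean and SD are retained in a
`StandardizationRecord`, serialized alongside fitted models, so effects can
always be mapped back to raw units.

The real-world effect of a raw-unit change `delta_x` in predictor x with
standardized coefficient beta and raw SD sigma is the multiplicative factor

    factor = (exp(beta / (2 sigma)))^delta_x,

reported as a percent change `(factor - 1) * 100`. Confidence bounds push
the Wald interval `beta +/- z * SE` through the same transformation
(endpoint transformation). The resulting percent interval is asymmetric
around the point estimate — the standard behaviour for log-link effects; a
symmetric-percent presentation would require a delta-method linearization,
which is not used here. Predictors that entered the model unstandardized
use a pass-through record with 2 sigma = 1, so one code path serves both.

Coefficient (forest) plots show standardized coefficients with up to three
nested Wald intervals (85% and 95% by default — the tighter level
surfacing trends worth follow-up, the wider one conventional confidence);
no p-value-based significance flagging is produced anywhere.

## Model selection

Two deliberately separate lines of evidence per taxon:

* **AIC** (2k - 2 logL, k counting beta, gamma, dispersion and sigma_b)
  across the candidate grid, by default {poisson, nbinom1, nbinom2} x
  {ZI, no ZI}. Ties break toward fewer parameters, then Poisson < NB1 <
  NB2, then non-ZI — the simpler model wins when the data cannot
  distinguish. Unconverged candidates are listed but never selected.
* **Mean-variance diagnostics**: counts aggregated by caller-chosen
  covariate combinations (site, site x year, ...); per-group (mean,
  variance) points overlaid with the three families' variance curves.
  Curve dispersion is summarized by weighted least squares (weights =
  group sizes): phi_hat is the origin-constrained WLS slope of variance on
  mean (clamped at >= 1), 1/theta_hat the WLS slope of (variance - mean)
  on mean^2 (clamped positive). These curves summarize the scatter; they
  are not the MLE dispersion. The "visually best" curve is operationalized
  as lowest weighted SSE with a 5% parsimony tolerance: a simpler family
  whose SSE is within 5% of the minimum is preferred, since curves that
  close are visually indistinguishable (and the nested families can always
  shave SSE by epsilon).

The pipeline reports both verdicts and leaves the decision to the caller or
config; when they conflict, the package's documented convention is to trust
the mean-variance plot.

## Residual diagnostics

Goodness of fit uses simulated (randomized-quantile) residuals: for each
observation, `n_sim` (default 250) responses are simulated from the fitted
model and the observation's randomized PIT position among them,

    u_i ~ Uniform(n_below, n_below + n_equal + 1) / (n_sim + 1),

is Uniform(0,1) when the model is correct, regardless of the family.
Simulation is *unconditional* by default — fresh random intercepts drawn
from N(0, sigma_b_hat^2) per replicate — the stricter check, because
conditioning on the estimated modes absorbs group-level misfit; a
`conditional=True` option holds the modes fixed. Randomness is keyed by
observation identity (seed, site, night, taxon) and by site for the
intercept streams, so residuals are reproducible and invariant to row
order.

Formal checks: Kolmogorov-Smirnov uniformity of the residuals; a
dispersion test comparing the variance of (y - sim mean)/sim SD against
the same statistic over the simulated replicates (two-sided empirical p);
and an outlier test comparing the count of observations outside the entire
simulated range with its Binomial(n, 2/(n_sim+1)) reference — conservative
for discrete data, where ties make escaping the simulated range harder
than the continuous bound suggests.

## Synthetic campaigns

The generator emulates a two-season acoustic monitoring campaign. The
default design has 36 sites and exactly 840 site-nights: 26 sites
monitored in year 0 totalling 276 nights and 27 sites in year 1 totalling
564 (17 sites in both years) — a realistic two-season effort in which
sites receive several short (5-6 night) deployments in the first season
and longer (13-14 night) redeployments in the second. Site-level
covariates (elevation ~ N(2073 m, 50 m), roost-structure index, lighting
indices, water distance, land-cover proportions) are drawn once per site;
night-level covariates (ordinal date over a June-September window, moon
illumination) per night; a binary year indicator enters unstandardized.
Ranges are package defaults chosen for plausibility, not biological
estimates. Counts are drawn from the configured family with a site random
intercept (sigma_b = 0.6 by default) and optional logit-linear structural
zeros. Linear predictors use the *generating* mean/SD of each covariate
(for the discrete-uniform ordinal date, the discrete variance
((range+1)^2 - 1)/12), so fitted scale2 coefficients are directly
comparable to the configured truth.

What the generator does not emulate: spatial covariance among sites,
temporal autocorrelation within deployments, detection differences among
recorders, or any real taxon's parameter values. Passing recovery and
calibration tests on these data demonstrates correctness of the estimator
and diagnostics under the assumed model, not robustness to those real-data
features.

## Numerical choices

* Quadrature: 7 nodes default; inner Newton tolerance 1e-10 on the scaled
  gradient, curvature floored at 1e-10; linear predictors clipped at
  +/- 700 before exponentiation.
* Optimizer: L-BFGS-B ftol 1e-12, gtol 1e-6, then Newton polish to
  gradient max-norm < 1e-9 (up to 12 steps, Hessian refreshed at most
  twice).
* scale2 uses compensated (two-pass) centering so the mean-zero contract
  holds to 1e-12 even for small-variance predictors riding on large
  offsets.
* Ties in AIC and in the mean-variance SSE break toward simplicity, as
  above; distfit groups of size < 2 are dropped (count logged) and fewer
  than 3 usable groups is an error suggesting coarser aggregation.
* Rows with missing model covariates are dropped with a logged count.
  Dates should be converted to integer ordinal day before standardization.
* Zero counts for sampled-but-undetected taxa must be explicit rows; the
  package does not impute absent site-night x taxon combinations.

## Test problem sizes

The simulation-based checks run at the campaign scale the package targets
(36 sites / 840 site-nights / 10 covariates): 200 replicates for parameter
recovery and residual calibration (the type-I band is the binomial 99%
interval at 200 draws), 25 replicates per generating family for the
six-candidate selection study, and 40 for the dispersion-power check.
Zero-inflated candidates in the selection study use a date-only ZI formula,
keeping the candidate grid's cost proportionate while still exercising the
mixture path.
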