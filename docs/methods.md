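# Methods

## The model

For one individual and one autosome, let `y_p` be the population-normalized
methylation residual (M-value minus the cross-sample probe mean, divided by
the cross-sample probe sd) at base-pair position `p`. The model is a latent
Gaussian field with independent measurement noise:

    y_p | mu_p, sigma0^2  ~  N(mu_p, sigma0^2)          (likelihood)
    mu = beta + xi                                      (latent structure)
    xi  ~  N(0, Q^{-1}(tau, kappa))                     (Matern field)

The field covariance is Matern with smoothness `lambda`:

    Cov(xi(p1), xi(p2)) = sigma^2 / (Gamma(l) 2^{l-1})
                          * (kappa |p1-p2|)^l K_l(kappa |p1-p2|)

`lambda` is fixed at 0.5 throughout the pipeline, giving exponential decay
`sigma^2 exp(-kappa d)`. Two derived parameters are used for
interpretation: the range `r = sqrt(8 lambda)/kappa` (distance of ~0.1
correlation; for `lambda = 0.5`, correlation `exp(-2)` at `d = r`) and the
marginal sd `sigma`, related to the precision-like scale `tau` by the 1-D
convention

    sigma^2 = Gamma(l) / (Gamma(l + 1/2) * sqrt(4 pi) * kappa^{2l} * tau^2),

which for `lambda = 0.5` reduces to `sigma^2 = 1/(2 kappa tau^2)`. This
convention is fixed by the prior calibration below: a range of 3000 bp and
`sigma^2 = 1` give `kappa_m = 2/3000 ~ 0.00067` and
`tau_m = sqrt(750) ~ 27.39`. (The alternative `4 pi` normalization is
inconsistent with those calibrated values and is not used.)

Priors (the standard vague settings for this model family):
`beta ~ N(0, 1e6)`; `1/sigma0^2 ~ Gamma(1, 5e-5)`;
`log tau ~ N(log tau_m, precision 0.05)`;
`log kappa ~ N(log kappa_m, precision 0.05)` (precision 0.05 = variance 20).

## Exact inference by Markov representation and grid quadrature

The `lambda = 0.5` field is an Ornstein-Uhlenbeck process, hence Markov: on
any strictly increasing positions its precision matrix is tridiagonal with
entries driven by the lag correlations `rho_i = exp(-kappa (p_{i+1}-p_i))`,
and its inverse is exactly the dense exponential covariance. Because the
likelihood is Gaussian, the field and the intercept are marginalized
analytically; `log p(y | tau, kappa, sigma0)` is computed in O(n) per
hyperparameter value by an LDL factorization of the tridiagonal
`T = Q + phi I` (`phi` the noise precision) with a Schur complement on the
intercept. The Schur complement is evaluated in the cancellation-free form
`s = 1/V_beta + phi u' Q 1` (`u = T^{-1} 1`), which stays accurate as
`phi -> infinity`. This replaces any finite-element/SPDE approximation by an
exact computation; equivalence with a dense multivariate-normal oracle is
part of the test suite (1e-6 absolute on tracks up to n = 100).

The 3-D posterior over `(log tau, log kappa, log phi)` is evaluated on a
21-node-per-dimension product grid and normalized by log-sum-exp. The
initial grid spans the prior mean +/- 4 prior sds for `log tau` and
`log kappa`; the noise dimension spans the log precision of the raw
residual variance +/- 6, extended to the Gamma prior's high-precision peak
at `log(shape/rate)` (see "Bimodality" below). Because the vague priors
make this initial grid coarse relative to the posterior, the grid is then
adapted iteratively: it is widened (factor 2, capped at twice the initial
span) while more than 0.5% of mass sits on a dimension's outer slabs,
re-centered and shrunk while a dimension's node spacing exceeds half its
posterior sd, and finally validated against a 3x-wider grid — if the
moments move, the wider grid is adopted and adaptation continues. A fit
whose final grid still holds more than 5% of mass on the boundary carries a
`boundary_flag`. Posterior means and sds of `log tau` and `log kappa` are
weight-averaged node values; the intercept and `sigma0^2` are conditional
posterior means averaged over the grid. Agreement with a long-run adaptive
Metropolis sampler (within 0.05 log-units on n <= 300 tracks) is tested.

Derived `r` and `sigma` are, by default, transforms of the posterior means
of `log kappa` and `log tau`; the node-wise transform-then-average
alternative is also computed and can be selected
(`GridConfig(transform_convention="node_average")`). Fits are fully
deterministic: no randomness enters the inference.

### Bimodality under the vague noise prior

The Gamma(1, 5e-5) prior on the noise precision has its log-scale density
peak near `log(1/5e-5) ~ 9.9`, i.e. at `sigma0^2 ~ 5e-5`. On short or
weakly informative tracks the nugget is poorly identified and the posterior
develops a second, prior-driven mode in which `sigma0^2` collapses and a
shorter-range field absorbs the noise. This is a genuine property of the
model with these priors, not a numerical artifact (it is confirmed by dense
brute-force grids and MCMC). The grid adaptation above is designed to find
and integrate over that mode; it is also why the noise window always
reaches the prior peak.

### Model comparison: DIC

The plain (independence) model `y_p ~ N(beta, sigma0^2)` shares the same
priors and quadrature machinery (a 1-D grid over the log noise precision;
the intercept is conjugate). Both models are compared by a
marginal-deviance DIC: `D(theta) = -2 log p(y | theta)` with all latent
Gaussians integrated out, `D_bar` the posterior-weighted mean deviance,
`p_D = D_bar - D(theta_bar)` at the posterior-mean hyperparameters, and
`DIC = D_bar + p_D`. The comparison rule is
`delta = DIC_plain - DIC_dependency`, decisive beyond 4.

The conditional-deviance flavor (deviance at plug-in conditional means of
the latent field) is *not* used: in the collapsed no-nugget mode described
above the conditional deviance diverges to minus infinity — a model with a
vanishing conditional residual variance looks perfect — so it would declare
spatial dependency even on white noise. With the marginal deviance the
penalty acts on the hyperparameters; iid tracks come out indeterminate
(|delta| < 4) and spatially dependent tracks are decisively favored, which
is the behavior the comparison is meant to capture. Under this flavor the
plain model's `p_D` is close to 1 (the noise precision; the intercept is
marginalized), which the tests assert against an independent quadrature
oracle.

The variance explained by the spatial field is
`1 - sigma0^2(dependency)/sigma0^2(plain)` on posterior means, deliberately
not clipped below zero.

## Preprocessing

Beta values (strictly in (0,1)) are transformed to M-values with logit2;
probes must have a call rate of at least 95% across samples (configurable);
population normalization subtracts the cross-sample probe mean and divides
by the unbiased (n-1) sample sd, so unit-variance residuals match the
`sigma^2 = 1` prior calibration. Probe-type (Infinium I/II) normalization
such as BMIQ is assumed to have been applied upstream and is not
reimplemented. Missing values propagate as dropped positions (the model
conditions on observed sites only); tracks with fewer than 50 sites are
skipped as unidentifiable. Positions are 1-based base pairs from the
manifest; duplicate (chromosome, position) entries are rejected rather than
jittered.

## Cohort statistics

*Consistency across chromosomes* is quantified by the one-way
random-effects ICC(1,1) — `(MSB - MSW)/(MSB + (k-1) MSW)` with chromosomes
as replicates, the standard unbalanced correction `k0` for unequal
replicate counts, and an F-distribution confidence interval — computed on
one randomly selected individual per family (selection seed recorded).

*Batch and biology contrasts* use squared differences of posterior-mean log
parameters between paired individuals, per chromosome:
`D_{tau,j} = (log tau_{A,j} - log tau_{B,j})^2` and likewise for kappa.
Four pairing schemes are built: true co-twin pairs; random pairs; random
pairs matched on conversion plate; random pairs matched on plate and
BeadChip. Random schemes draw 100 pairings (seeded); the representative
pairing is the repeat whose median D (of log tau, the variance-controlling
parameter) ranks ceil(100/2) among the repeats. Non-twin schemes never pair
true co-twins — otherwise the scheme contrasts would be contaminated —
and odd strata leave one sample unpaired. Eight one-sided contrasts are
tested (scheme-vs-scheme, MZ/DZ by same/different chip, DZ vs MZ, and
opposite- vs same-sex DZ pairs), each with a Mann-Whitney test per
chromosome (exact enumeration for m+n <= 20 without ties, midrank normal
approximation otherwise).

*Combination across chromosomes* uses the Brown-family extension of
Fisher's method for correlated tests: `X = -2 sum ln p_j` is referred to a
scaled chi-square `c chi2_f` matching `E[X] = 2k` and
`Var(X) = 4k + 2 sum_{i<j} cov_ij`, with
`cov_ij = 3.263 rho + 0.710 rho^2 + 0.027 rho^3` (the Kost-McDermott
polynomial) and `rho_ij` the Pearson correlation between chromosomes of the
per-individual statistic being tested. At zero correlation this is exactly
Fisher's method; null calibration under correlated statistics is verified
by simulation (KS test over 2000 replicates).

*Chromosome profiles*: each individual's range estimates are divided by
their within-individual median; the per-chromosome median of these relative
ranges is correlated (Spearman, Fisher-z CI with sd `1/sqrt(n-3)`) with
relative per-chromosome covariates — the proportion of island probes from
the manifest, and a user-supplied gene-density table (a synthetic fixture
ships with the tests; real values are user input).

*Age contrast*: individuals under 40 vs over 50, per chromosome and
parameter, one-sided Mann-Whitney with the direction the model anticipates
(lower log tau, i.e. more spatial variance, and higher variance-explained
in the older group), combined across chromosomes as above.

## The synthetic cohort

The simulator generates what the analysis consumes: a beta-scale matrix,
manifest and sample sheet, plus a ground-truth table of every parameter
used. Structure mirrors a twin-register 450k study at desk scale:

- **Positions**: 12-16 islands per chromosome (varying deterministically
  by chromosome so island proportions differ) of ~11 sites at 30 bp
  spacing, on a background of ~1500 bp jittered gaps — roughly a third of
  sites in islands, as on the 450k array. The dense within-island spacing
  matters: the exponential field's short-range roughness can impersonate a
  noise nugget, and close CpG pairs are what separates the two; with
  sparse islands the short-range individuals in the cohort are
  unidentifiable and their fits collapse.
- **Population means**: bimodal on the beta scale (Beta(2,8)/Beta(8,2)
  mixture), residuals added on the M scale and mapped back by inverse
  logit2 — mirroring the direction of the real preprocessing.
- **Dependency parameters**: individuals are drawn in
  `(log sigma^2, log kappa)` space — `log sigma^2 ~ N(log 0.75, 0.25)`,
  `log kappa ~ N(log 0.00067, 0.3)`, `log tau` derived via
  `sigma^2 = 1/(2 kappa tau^2)` — so the field-to-noise variance ratio
  stays in the identifiable regime (independent tau/kappa draws would let
  the field share vary by e^(+/-3) and push many tracks into the collapsed
  mode). The mean field variance 0.75 plus noise (`sigma0 = 0.5`) gives
  unit total variance like normalized residuals. Per-chromosome scatter is
  0.12, co-twin correlation 0.85 (MZ) / 0.45 (DZ).
- **Batch and biology shifts** act along the constant-`sigma^2` ridge
  (`delta log kappa = -2 delta log tau`), matching the observed linear
  relationship of plate effects in the (log tau, log kappa) plane and
  leaving the field share — hence identifiability — untouched: plate sd
  0.15 (one outlier plate with a -0.4 log-tau, +0.25 log-kappa shift and a
  +0.2 intercept shift), BeadChip sd 0.08, a +/-0.3/2 sex shift and a
  -0.25 log-tau shift for the older group (which *raises* the field
  share, the direction the age analysis anticipates). Sizes come from a
  power calculation: each contrast's squared-difference increment must
  exceed the D noise floor `2 (chrom_sd^2 + estimation_sd^2) ~ 0.07` at
  the group sizes the cohort layout implies.
- **Cohort layout**: 200 families (MZ fraction 336/604), 26 pairs per
  plate, 12 samples per chip with 80% of pairs on one chip, two age groups
  (23 +/- 3 vs 62 +/- 7 years, ~26% old, none in between), DZ same-sex
  fraction 175/268, 1% missingness.
- **Field draws** use the exact Markov conditional recursion
  `xi_{i+1} = rho_i xi_i + sigma sqrt(1-rho_i^2) z`, so the simulated
  marginal variance and lag correlations are exact (verified by Monte
  Carlo in the tests).

Default problem sizes are 5 chromosomes x 400 sites per chromosome. The
site count matters qualitatively: below roughly 300 sites the nugget is
weakly identified and a non-negligible share of tracks falls into the
collapsed no-nugget posterior mode, which makes posterior-mean estimates
heavy-tailed; at 400 sites collapse is rare and the per-track estimation
error sd is ~0.12 log-units, well below the simulated effect sizes. At
these sizes every cohort contrast (plate, chip, zygosity, sex, age) is
detectable by the pipeline at 200 families, while a full simulate-fit-test
cycle stays a desk-scale computation (cohort-scale fits use a 15-node
adaptive grid; single-track work defaults to 21 nodes). Effect sizes are
synthetic: the cohort they emulate publishes test results, not effect
magnitudes, so the defaults were chosen once for detectability and are
documented here rather than tuned to any external value.

What passing the synthetic tests does *not* show: the generator draws
Gaussian fields that match the model family exactly, so recovery results
certify the inference machinery, not robustness to model misspecification
(non-Gaussian residuals, nonstationary dependency within vs outside
islands, cell-composition effects, probe-chemistry artifacts — all absent
from the simulation).

## Numerical choices and limitations

- Degenerate hyperparameter nodes (overflow/underflow at absurd
  parameter values reached only by grid widening) report vanishing
  likelihood instead of propagating non-finite values.
- `1 - rho^2` is computed as `-expm1(-2 kappa gap)` (accurate for tiny
  `kappa gap`) and floored at 1e-300.
- Log-determinants accumulate in chunked products to avoid one `log` per
  site per node.
- The plain model uses 1201 noise nodes over +/-8 log-units so its
  posterior is never quantization-limited relative to the dependency fit.
- Tracks shorter than ~100 sites give posteriors dominated by the priors;
  the minimum track size (50) is a hard floor, not a recommendation.
- Chromosomes X/Y, raw-intensity QC, probe blacklists and island-dependent
  (nonstationary) dependency are out of scope; the last is the natural next
  model extension.
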