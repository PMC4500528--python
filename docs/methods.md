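# Methods

## Problem and model

`gembayes` analyzes retrospective case-control studies of gene-environment
interaction in which (i) several genetic markers in moderate linkage
disequilibrium (LD) enter the risk model directly as genotypes, without
haplotype-phase inference, and (ii) the binary environmental exposure is
observed with misclassification.

Disease risk follows a polytomous logistic model; with binary disease
(`K = 1`, the case shipped in every experiment) and no exactly measured
covariates:

    logit pr(D = 1 | G, T) = beta_0 + beta_T T
        + sum_i A_i beta_Ai + sum_i T A_i beta_ATi        (additive block)
        + sum_i B_i beta_Di + sum_i T B_i beta_DTi        (dominance block)

`A_i = (allele-M dosage) - 1` takes values -1/0/+1, and `B_i` is the
zero-mean dominance code `(-P_mi^2, P_Mi P_mi, -P_Mi^2)` for the genotypes
(m_im_i, M_im_i, M_iM_i).  The *genotype effect model* (GEM) carries both
blocks; the *additive effect model* (AEM) drops the dominance block.  Under
Hardy-Weinberg equilibrium the codes have closed-form moments — notably
`E(B_i) = 0`, `Cov(A_i, A_j) = 2 Delta_ij`, `Cov(B_i, B_j) = Delta_ij^2`,
`Cov(A, B) = 0` — which the package verifies exactly against full enumeration
of the genotype distribution.

### Multilocus genotype distribution

The joint genotype law is parameterized by allele frequencies `P_Mi` and
pairwise LD coefficients `Delta_ij` (covariance of allele indicators on one
haplotype).  Haplotype frequencies use the Bahadur-style truncation with all
third- and higher-order disequilibria set to zero:

    h(a) = prod_k p_k(a_k) + sum_{i<j} Delta_ij s_i s_j prod_{k != i,j} p_k(a_k)

with sign `s_k = +1` when the pattern carries allele M at marker k.  This is
the simplest family reproducing every moment the method uses (margins,
pairwise Delta, and the code covariances above, all exactly).  Genotypes are
sums of two independent haplotype draws (HWE at the haplotype level).
Infeasible `Delta` configurations (a negative implied haplotype frequency)
raise an error naming the offending allele pattern.  Joint enumeration is
capped at 10 markers (3^10 genotype vectors) with an explicit capacity
error; the pseudolikelihood denominator enumerates this set.

### Exposure misclassification

The observed exposure X is linked to the latent truth T by the
nondifferential model with false-negative probability
`xi0 = pr(X=0 | T=1)` and false-positive probability `xi1 = pr(X=1 | T=0)`;
identifiability requires `xi0 + xi1 < 1`.  `xi` is treated as known in all
fitters; uncertainty about it is addressed by the sensitivity sweep (refit
over a grid of assumed `(xi0, xi1)`), not by an extra prior block.  A
pluggable hook accepts differential models `p(x | t, g, z, d)` validated
for normalization; the shipped fitters use the nondifferential form.

### Retrospective pseudolikelihood

Case-control sampling is modeled through intercept offsets
`kappa = beta_0 + log(n_1/n_0) - log(pi_1/pi_0)` absorbing the sampling
fractions and the population prevalence `pi`.  Each subject contributes

    L_i = sum_t S(d, g, t) p_miss(x | t) f_T(t)
          / sum_{k, t, g*} S(k, g*, t) f_T(t),

    S(k, g, t) = exp[1(k>=1){kappa + m(g, t)}]
                 / (1 + exp{beta_0 + m(g, t)}) * pr(g; Theta),

with the latent exposure summed against the misclassification model and
genotype vectors containing missing calls additionally summed over their
compatible completions.  Maximizing `sum_i log L_i` over the risk
coefficients, `eta = pr(T=1)`, and the genotype parameters
`Theta = (P_M, Delta)` yields consistent, asymptotically normal estimates;
conditioning on Z keeps the criterion free of the covariate density.

Everything is evaluated in log space with log-sum-exp, which removes any
need for extended-precision arithmetic even when linear predictors are
large.  Subjects are collapsed to distinct `(d, x, z, genotype-pattern)`
cells, so one evaluation costs O(3^I) regardless of sample size; a generic
(readable) evaluation path and a vectorized fast path are both kept and
tested for exact agreement, alongside an explicit triple-loop oracle at one
marker.

## Fitting

**Pseudo-MLE.**  Quasi-Newton (BFGS) with numerical gradients on an
unconstrained reparameterization: logits for `eta` and each `P_M`, and a
scaled logit mapping each `Delta_ij` into its pairwise feasibility box
(which moves with the current allele frequencies); jointly infeasible
proposals are rejected by a penalty.  Gradient tolerance 1e-8; convergence
is additionally accepted when the final unconstrained gradient norm is below
0.05 (the BFGS "precision loss" exit with numerically flat gradients).
Starting values come from the naive logistic fit, control-sample genotype
parameters, and the method-of-moments deconvolution
`eta0 = (mean(X) - xi1)/(1 - xi0 - xi1)`.  When `pi` is supplied, `beta_0`
is tied to `kappa` through the sampling identity; otherwise both are free.

**Sandwich covariance.**  `H^{-1} V H^{-1}` with `H` minus the Hessian of
the total log pseudolikelihood (central differences) and
`V = sum_d n_d Cov_d(Psi)` the within-stratum score variance — equivalently
`n(Sigma_hat - Lambda_hat)` with the case-control correction
`Lambda_hat = sum_d (n_d/n) mean_d(Psi) mean_d(Psi)^T`.

**Naive comparator.**  Prospective logistic regression of D on
(X, A, B, interactions), treating X as the true exposure; dominance codes
use control-sample allele frequencies.  Conventions for quantities the
naive model does not directly estimate: the reported `kappa` is the
logistic intercept (its retrospective estimand) and `p_m` are the
control-sample allele frequencies.

**Posterior sampling.**  The posterior multiplies the pseudolikelihood by a
normal prior on the risk coefficients (default `N(0, 3^2 I)`; optionally
the LD-structured covariance proportional to `blockdiag(V_A, V_D)`),
uniform(0,1) priors on `eta` and each allele frequency, and flat priors on
`kappa` and each `Delta` within its feasibility box (the box's mild
dependence on `P_M` is ignored in the prior normalizer).  Sampling uses a
blocked Gaussian random walk on the unconstrained scale with the Jacobian
correction: the exposure/additive coefficients, the dominance coefficients
and the nuisance block (eta, allele frequencies, LD) are updated in a
systematic scan, each block's proposal covariance seeded from the
corresponding block of the approximate posterior covariance
`(vcov_MLE^{-1} + prior precision)^{-1}`, rescaled per block during burn-in
toward acceptance 0.2-0.4, blended with the empirical covariance of recent
draws, then frozen.  (A full-vector proposal and a fitted independence
kernel were both tried and mix worse: the dominance block is weakly
identified and skewed at moderate n, which defeats a global Gaussian
approximation.)  Default 20,000 sweeps with 5,000 burn-in — split-Rhat
stays below 1.05 on the shipped designs — while the replicate experiment
runner uses shorter chains (noted below); point estimates are posterior
means; seeds are recorded in every artifact and identical seeds give
identical chains.

**Asymptotic posterior.**  Gaussian approximation with
`Sigma_n = (I_n + J)^{-1}` and `M_n = Sigma_n (I_n theta_hat + J theta_0)`,
where the data precision `I_n` is the inverse sandwich covariance (so a
flat prior reproduces pseudo-MLE inference exactly — the sample-size
convention adopted here), `J` is minus the Hessian of the log prior
(diagonal `1/sd^2` on normal-prior coordinates, zero on flat/uniform ones),
and `theta_0` is the prior mode (the MLE itself on flat coordinates, where
`J` vanishes and the choice is inert).  Two per-observation information
estimators are exposed for audit: the Hessian-based `-n^{-1} Hessian` and
the moment identity `Sigma_hat + Lambda_hat`; they agree within ~10% at
n = 5,000 in simulation.

## Coverage validity check

Because the pseudolikelihood is not a true likelihood, posterior
probability statements need empirical validation.  The check draws the
monitored coefficients from their prior, regenerates data under each draw,
refits the posterior by MCMC, and records `H_k` — the posterior CDF at the
drawn truth, computed from the chain with the mid-rank `(r + 0.5)/(N + 1)`
convention (avoids exact 0/1 and is invariant under monotone
reparameterization).  Under a coverage-proper likelihood `H ~ uniform(0,1)`;
a Kolmogorov-Smirnov rejection invalidates the criterion.  Two analytic
controls calibrate the machinery: a Beta-binomial conjugate model (proper;
H exactly uniform) and its temperature-corrupted version (likelihood
power 0.5; KS rejects with power increasing in m).  The scenario battery is
configuration, not hard-coded: the shipped default is the small
additive-model design at reduced size (120/120, m >= 50) for speed.

## Synthetic-data generator

The generator emulates the shipped study conditions: three markers with
`P_M = 0.25` and all pairwise `Delta = 0.03`; `T ~ Bernoulli(0.5)`;
misclassification `xi0 = 0.20`, `xi1 = 0.25`; logistic disease model with
population prevalence `pi = 0.005`; equal case/control quotas (1,500/1,500
for the large GEM design, 350/350 for the small AEM design); optional MCAR
genotype masking.  `beta_0` is calibrated by 1-D root finding so the
population-averaged risk equals `pi`; the large-design true coefficients
are `beta_X = 0.693`, `beta_A = (0.406, 0.789, 0.693)`,
`beta_AX = (0.916, 0.693, 1.099)`, `beta_D = (0.262, 0.095, 0.693)`,
`beta_DX = (1.099, 0.916, 1.099)`, and the small additive design uses
`beta_X = 1.099`, the same `beta_A`, `beta_AX`.

Retrospective sampling is implemented by drawing each stratum directly from
the population conditional law `pr(G, T | D = d)` computed on the
`(genotype, exposure)` grid.  This is distribution-identical to
rejection-until-quota sampling of iid population subjects — the accepted
members of each stratum are iid draws from that conditional law — and a
rejection sampler is retained and tested against the conditional one.  The
generator does not emulate population stratification, related individuals,
genotyping error, or exposure models beyond a Bernoulli `T` independent of
`G`; passing tests therefore speak to the estimator's behavior under the
model's own assumptions, not to robustness against their violation.

## Numerical choices

- Log-space kernels throughout; explicit max-shift log-sum-exp in the hot
  path.
- Numerical derivatives: central differences, relative step 1e-5 for
  scores/gradients and 1e-4 for Hessians, on the natural scale at interior
  points (boundary parameters are refused).
- Singular posterior precision falls back to a ridge-regularized inverse
  with a warning; singular LD prior blocks fall back to their diagonal.
- Ties in the H statistic take half weight (mid-rank).
- Degenerate inputs: empty strata, non-binary X, genotype values outside
  {0,1,2,NA}, infeasible Delta, unattainable target prevalence, and
  `xi0 + xi1 >= 1` all raise typed errors naming the offense.

## Experiment scales

The replicate experiments shipped in the test-suite and the acceptance
script run at desk scale, chosen once: 500 replicates for the naive and
small-sample pseudo-MLE bias experiments, 100 replicates for the large
pseudo-MLE and asymptotic-posterior experiments, and 25 replicates with
6,000-iteration chains for the MCMC comparison.  Monte-Carlo standard
errors accompany every bias/RMSE entry, and the experiment runner also
reports the squared-error (MSE) scale alongside the RMSE.

## Known limitations

- Fitting is implemented for binary disease (K = 1); the kernels accept
  general K.
- Gene-environment dependence (genotype distributions stratified by
  environment) is out of scope; G and (T, Z) are assumed independent in the
  population.
- `xi` is never estimated from replicate or validation data; only known-`xi`
  fits and sensitivity sweeps are provided.
- The LD prior uses the code covariance as a structural template; it is a
  modeling convenience, not an estimate of coefficient covariance.
- With heavy misclassification and small samples the sampling distribution
  of the risk estimates is skewed; the Gaussian asymptotic posterior is not
  recommended there — use the MCMC fit.
- When the pseudo-MLE itself is numerically stable, the posterior mean
  under the default weak `N(0, 3^2 I)` prior shrinks it only negligibly at
  the shipped sample sizes (shrinkage factor about 0.99); the Bayesian fit
  then matches, rather than improves on, the pseudo-MLE's replicate error.
  Material shrinkage benefits require genuinely informative priors or
  unstable likelihood optima.
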