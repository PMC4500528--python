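# gembayes

Genotype-based Bayesian pseudolikelihood analysis of gene-environment
interactions in case-control studies, for settings where

- several genetic markers in moderate linkage disequilibrium (LD) enter the
  risk model directly as unphased genotypes (no haplotype-phase inference),
  and
- the binary environmental exposure is misclassified, with known
  false-negative probability `xi0 = pr(X=0 | T=1)` and false-positive
  probability `xi1 = pr(X=1 | T=0)`.

It is aimed at statistical geneticists and epidemiologists analyzing
retrospective case-control data (e.g. addiction, cancer, or other complex
diseases) where ignoring exposure error visibly attenuates interaction
estimates.

## Model

Disease risk follows a logistic model in the exposure `T`, the additive
genotype codes `A_i in {-1, 0, 1}` (allele dosage minus one), the zero-mean
dominance codes `B_i in {-P_m^2, P_M P_m, -P_M^2}`, and their products with
`T` (the *genotype effect model*; the *additive effect model* drops the
dominance block):

    logit pr(D=1 | G, T) = beta_0 + beta_T T + sum_i (A_i beta_Ai + T A_i beta_ATi)
                                    + sum_i (B_i beta_Di + T B_i beta_DTi)

Retrospective sampling and the latent true exposure are handled by a
pseudolikelihood: each subject contributes

    pr(D, G, X | Z, R=1) = sum_t S(D, G, t) p_miss(X | t) f_T(t)
                           / sum_{k, t, g} S(k, g, t) f_T(t)

where `S` combines the risk kernel (with the case-control offset
`kappa = beta_0 + log(n_1/n_0) - log(pi_1/pi_0)`) and the multilocus
genotype distribution built from allele frequencies and pairwise LD under
Hardy-Weinberg equilibrium.  On top of the pseudo-MLE (with sandwich
standard errors) the package provides a Metropolis-Hastings posterior
sampler with a normal prior on the risk coefficients, a Gaussian
large-sample posterior approximation, and a posterior-coverage validity
check (H-statistic / Kolmogorov-Smirnov uniformity).  See
`docs/methods.md` for the full account.

## Worked example

```python
import gembayes as gb
from gembayes.estimators import NaiveLogisticGxE, PseudoMLE
from gembayes.io import data_to_frame

# simulate one study: 1,500 cases / 1,500 controls, three markers with
# P_M = 0.25 and pairwise LD 0.03, exposure misclassified at (0.20, 0.25)
scenario = gb.experiment1_scenario()
data = gb.simulate_case_control(scenario, rng=1)

df = data_to_frame(data)
X = df.drop(columns=["D"]).rename(columns={"X": "x"})
y = df["D"].to_numpy()

naive = NaiveLogisticGxE().fit(X, y)
corrected = PseudoMLE(xi0=0.20, xi1=0.25, prevalence=0.005).fit(X, y)

print("true beta_X                 0.693")
print(f"naive beta_X              {naive.estimates_['beta_x']:7.3f}")
print(f"pseudo-MLE beta_X         {corrected.estimates_['beta_x']:7.3f}"
      f"  (SE {corrected.se_['beta_x']:.3f})")
```

Output:

```
true beta_X                 0.693
naive beta_X                0.325
pseudo-MLE beta_X           0.620  (SE 0.150)
```

The naive logistic fit, which treats the error-prone exposure as the truth,
attenuates the exposure effect by roughly half; the pseudo-MLE, which sums
the latent true exposure out of the likelihood with the known
misclassification probabilities, recovers it (up to sampling noise, here
about half a standard error below the truth).

The same machinery is available from the command line:

```bash
gembayes simulate --scenario experiment1 --seed 1 --out run/
gembayes fit-mle --data run/data.csv --xi0 0.2 --xi1 0.25 \
    --prevalence 0.005 --out run/
gembayes sensitivity --data run/data.csv --prevalence 0.005 \
    --xi0 0.0 --xi0 0.2 --xi1 0.25 --out run/
```

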