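# dpmlpa

Latent profile analysis (LPA) groups people into discrete profiles — for
example, subgroups of adolescents with similar patterns of neurocognitive
task scores — from a table of continuous indicator variables.  The perennial
problem with conventional LPA is choosing the number of profiles: fit
criteria (AIC, BIC, bootstrap likelihood ratio tests) reward ever more
profiles, while interpretability and classification certainty degrade as
redundant profiles accumulate.

`dpmlpa` implements a non-parametric Bayesian resolution: **DPM-LPA**, a
Dirichlet process mixture with the LPA likelihood

    x_{j,i} | z_i = t  ~  N(mu_{j,t}, 1/xi_j)          (shared diagonal covariance)
    z_{1:n}            ~  DP(alpha),  alpha inferred
    xi_j ~ Gamma(5, 5),   mu_{j,t} | xi_j ~ N(0, 2/xi_j)

fitted by truncated stick-breaking mean-field variational Bayes.  The DP
prior penalizes each additional occupied profile in proportion to its size,
so the fitted model keeps only profiles that earn their keep in likelihood;
profiles that are no participant's most probable assignment are dropped.
The package also provides, for comparison and validation:

- conventional maximum-likelihood LPA by EM, with AIC/BIC, the parametric
  bootstrap likelihood ratio test (BLRT), and a finite Bayesian LPA
  (symmetric Dirichlet prior) selected by ELBO;
- the entropy reduction statistic (classification certainty) and pairwise
  Mahalanobis profile distances (distinctiveness);
- Bayes-factor validation of profiles against outcome variables under a
  conjugate normal-gamma model: ANOVA-style BF10, exhaustive set-partition
  post-hoc search over equal-mean groupings, per-profile posterior means
  with 95% credible intervals, and an r² effect size;
- a simulation benchmark for class-enumeration accuracy.

It is written for applied researchers in psychology / psychiatric
epidemiology doing person-centered analysis of standardized test batteries.

## Worked example

```python
import numpy as np
from dpmlpa import fit_dpm, entropy_reduction, distance_summary, analyze_outcome
from dpmlpa.io_config import IndicatorMatrix, standardize_columns

rng = np.random.default_rng(0)
centers = np.array([[-1.5]*6, [0.0]*6, [1.5]*6])
labels = np.repeat([0, 1, 2], [250, 150, 100])
x = centers[labels] + rng.standard_normal((500, 6))
data = IndicatorMatrix(values=standardize_columns(x))

state, profiles = fit_dpm(data, seed=1)          # no profile count supplied
y = 0.5 * (labels - 1) + rng.standard_normal(500)  # outcome tracking profiles
res = analyze_outcome(y, profiles.resp)
```

Output (printing the quantities above):

```
retained profiles: 3
counts: [251 150  99]
base rates: [0.501 0.301 0.198]
entropy reduction: 0.903
min/mean pairwise distance: 3.59 / 4.79
log10 BF10: 8.54 -> supports_H1
best partition: {1},{2},{3}
r2: 0.0926
  profile 1: mean -0.40  95% CrI [-0.53, -0.27]  n=251
  profile 2: mean +0.03  95% CrI [-0.14, +0.20]  n=150
  profile 3: mean +0.46  95% CrI [+0.25, +0.67]  n=99
```

The fit recovered the three generating profiles (unbalanced 250/150/100)
without being told the number, classified participants with high certainty
(entropy reduction 0.90; 1 = perfectly certain), and found the planted
outcome gradient: the Bayes factor decisively favors unequal outcome means
(log10 BF10 = 8.5), the best partition keeps all three profiles distinct,
and profile membership explains 9.3% of the outcome variance.

The same pipeline is available from the shell:

```
dpmlpa fit --data scores.csv --method dpm --seed 1 --out fit.json
dpmlpa select --data scores.csv --criterion bic --max-profiles 20 --seed 1 --out table.csv
dpmlpa outcomes --data scores.csv --fit fit.json --outcome externalizing --out report.json
dpmlpa simulate --n 250 --replicates 50 --methods dpm em_bic --seed 1 --out bench.csv
dpmlpa compare --data scores.csv --max-profiles 20 --seed 1 --out compare.csv
```

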