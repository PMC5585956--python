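# masem — two-stage meta-analytic SEM under unbalanced sample sizes

Meta-analytic structural equation modeling (MASEM) combines the correlation
matrices reported by k independent primary studies into one pooled matrix
(stage 1) and then fits a structural equation model to it (stage 2). This
package implements the four standard stage-1 synthesis methods and the
matching stage-2 fits for a four-variable recursive path model, together
with a Monte Carlo harness that asks a question of direct practical
relevance for meta-analysts in medicine and psychology: *what happens to
these methods when the primary studies are of very different sizes?*

## Model and methods

The path model has two exogenous variables (X1, X2), a mediator (Y1) and an
outcome (Y2):

    Y = Γ X + B Y + ζ,   Cov(X) = Φ,   Cov(ζ) = Ψ (diagonal)

with Γ the X→Y effects (γ22 ≡ 0), B strictly lower triangular (only the
Y1→Y2 path β21), so the model is recursive and over-identified with one
degree of freedom. Its implied covariance is the block matrix

    Σ(θ) = [ (I−B)⁻¹(ΓΦΓ′+Ψ)(I−B)′⁻¹   (I−B)⁻¹ΓΦ ]
           [ ΦΓ′(I−B)′⁻¹                Φ          ]

At the population values Γ = [[0.4, 0.5], [0.3, 0]], β21 = 0.5,
Φ = [[1, 0.2], [0.2, 1]], Ψ = diag(0.51, 0.51) this yields the population
correlation matrix with ρ = (0.65, 0.50, 0.58, 0.55, 0.35, 0.20), which
drives the homogeneous simulations; a second fixed matrix
ρ′ = (0.45, 0.30, 0.40, 0.35, 0.19, 0.15) generates heterogeneous studies.

Stage-1 synthesis methods:

* **UNIr** — element-wise n-weighted mean of raw correlations
  (Hunter–Schmidt), Bonferroni-adjusted at-least-one (BA1) homogeneity test
  on the r scale;
* **UNIz** — (n−3)-weighted mean of Fisher-z values, back-transformed
  (Hedges–Olkin), BA1 test on the z scale;
* **MGLS** — generalized least squares on the stacked correlation vectors
  with Olkin–Siotani large-sample weight matrices evaluated at a common
  pooled plug-in, Q_GLS homogeneity chi-square on 6(k−1) df;
* **TSSEM** — multigroup normal maximum likelihood under a
  common-correlation-matrix constraint, likelihood-ratio homogeneity test
  on 6(k−1) df.

Stage 2 fits the path model to the pooled matrix: the univariate methods
use normal-theory ML treating the pooled matrix as a covariance matrix on
the total sample size; the multivariate methods use WLS (ADF) on the
5-parameter correlation structure with the stage-1 asymptotic covariance
as weight, disturbance variances derived from the unit-variance
constraints. Both give a df=1 over-identification chi-square.

The simulation grid crosses k ∈ {5, 10, 15} studies, average sizes
n̄ ∈ {50, …, 1000}, heterogeneity fractions {0, 20%, 50%} and three
size-allocation designs holding k·n̄ fixed — equal (E), moderately unequal
(M: 60% of studies at 0.6·n̄, 40% at 1.6·n̄) and highly unequal (H: 40% at
0.4·n̄, 20% at n̄, 40% at 1.6·n̄); e.g. five studies averaging 50 subjects
become (30, 30, 30, 80, 80) under M and (20, 20, 50, 80, 80) under H.

## Worked example

Simulate one meta-analysis of five studies (n̄ = 100, highly unequal sizes),
pool by TSSEM and fit the path model by WLS:

```python
import numpy as np
from masem import SimCellConfig, simulate_meta, pool_tssem, fit_wls

studies = simulate_meta(SimCellConfig(k=5, nbar=100, design="H", seed=42), 0)
print(studies.sizes)                      # [40, 40, 100, 160, 160]
s1 = pool_tssem(studies)
print(np.round(s1.pooled, 3))             # [0.647 0.471 0.528 0.488 0.381 0.173]
print(round(s1.stat, 2), s1.df, s1.reject)  # 28.17 24 False
s2 = fit_wls(s1.pooled, s1.acov)
print({k: round(v, 3) for k, v in s2.estimates.items()})
# {'gamma11': 0.391, 'gamma12': 0.465, 'gamma21': 0.237, 'beta21': 0.54,
#  'phi12': 0.176, 'psi11': 0.566, 'psi22': 0.531}
print(round(s2.chisq, 2))                 # 4.32 on 1 df
```

The homogeneity LR statistic (28.17 on 24 df, p = 0.25) correctly retains
the common-matrix hypothesis for these homogeneous studies; the pooled
correlations sit near the population vector and the WLS estimates near the
generating parameters (γ11 = 0.4, γ12 = 0.5, γ21 = 0.3, β21 = 0.5,
φ12 = 0.2, ψ = 0.51).

The numbered scripts under `analysis/` run the full study: Type I error
(`02`), power under heterogeneity (`03`), pooled-correlation bias (`04`)
and stage-2 chi-square/parameter/SE summaries (`05`), each writing CSV
tables to `results/`. A small `masem` CLI (`masem stage1`, `masem stage2`,
`masem export-population`) applies the same estimators to user-supplied
correlation matrices in a CSV-directory exchange format.

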