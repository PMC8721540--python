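# nparrm — nonparametric rank inference for repeated measures with missing values

`nparrm` analyses repeated measures designs (each of *n* subjects observed
under *d* conditions or time points) in which some observations are
missing, without assuming normality, equal variances, or even a metric
scale: metric, count, ordinal and binary outcomes are all handled the same
way, and every procedure is invariant under strictly monotone
transformations of the data.

It is aimed at biostatisticians and applied researchers who need effect
estimates *with confidence intervals* from incomplete longitudinal data —
e.g. an ordinal symptom score measured over four visits where two thirds
of the patients drop out — and who do not want to discard incomplete
subjects or impute values.

## The model and effects

Subjects are i.i.d. vectors `X_k = (X_1k, …, X_dk)` with marginal
distributions `F_i` (normalized version: the average of the left- and
right-continuous CDFs, which handles ties). Missingness is carried by
indicators `λ_ik ∈ {0, 1}`; estimation uses *all available* observations
(`λ_i = Σ_k λ_ik` per condition, `N = Σ_i λ_i` in total) and is valid when
data are missing completely at random.

The treatment effect of condition *i* is the **unweighted relative
effect**

    p_i = P(Z < X_i) + ½ P(Z = X_i),   Z ~ G = (1/d) Σ_s F_s,

the probability that a value from condition *i* exceeds an independent
draw from the pooled reference distribution (`p_i = ½`: no tendency).
Because `G` weights every condition equally, `p` is a model constant even
when conditions have different amounts of missingness — unlike the
classical weighted effects `r_i = ∫ H_N dF_i`, whose reference `H_N`
depends on the observed counts.

On top of the estimator `p̂` the package provides

* a **positive semidefinite** estimator `V̂_n` of `Cov(√n (p̂ − p))` built
  from estimated influence functions (a sum of outer products, so PSD by
  construction; the classical rank-based estimator for `r̂` can lose
  positive semidefiniteness under missingness and is included as a
  comparator),
* global tests of `H₀: Cp = 0` for a contrast matrix `C`: the Wald-type
  statistic (χ² reference; liberal for small *n*) and two ANOVA-type
  statistics with Box/Greenhouse–Geisser moment matching (version 2, with
  an `F(f̂, (n−1)f̂)` reference, is the most accurate),
* a **multiple contrast test procedure (MCTP)**: statistics
  `T_ℓ = √n c_ℓ′p̂ / √(c_ℓ′V̂_n c_ℓ)` for every contrast row, joint
  calibration through the two-sided equicoordinate quantile of a
  multivariate t(n−1) (or normal) distribution with estimated correlation
  matrix, yielding simultaneous confidence intervals, compatible adjusted
  p-values and a global max-|T| test,
* a **simulation harness** (generators with six covariance patterns,
  MCAR/MAR mechanisms, complete-case and median-imputation comparators)
  for type-I error and power studies.

## Worked example

Three subjects, two conditions, one missing value:

```python
import nparrm as npr

ds = npr.worked_example()          # rows (1, 2), (3, NA), (2, 4)
eff = npr.unweighted_effects(ds)
print(eff.p_hat)                   # [0.375 0.625]
print(eff.r_hat)                   # [0.4   0.65 ]
print(eff.pairwise[0, 1])          # 0.75
```

`p̂ = (0.375, 0.625)`: values under condition 2 tend to be larger than a
draw from the pooled reference, condition 1 values smaller, and the
estimated probability that a condition-2 value exceeds a condition-1 value
(ties counted half) is 0.75.

A full analysis of the bundled synthetic four-session severity trial
(n = 135, ordinal 0–20 scores, heavy dropout) with all pairwise
comparisons:

```python
res = npr.mctp(npr.synthetic_severity_trial(seed=0),
               npr.tukey_contrast(4), alpha=0.05, approx="mvt", seed=42)
```

prints (via `examples/analyze_trial.py`):

```
            comparison  estimate              95% SCI     |t|   p adj
   session2 - session1    -0.114 [  -0.170,  -0.058]   5.238  0.0000
   session3 - session1    -0.165 [  -0.241,  -0.089]   5.554  0.0000
   session4 - session1    -0.037 [  -0.163,   0.089]   0.745  0.8675
   ...
global max-T = 5.554, global p = 0.0000 (reject the global null)
```

Each row is a session contrast on the probability scale with its
simultaneous 95% confidence interval; intervals entirely below zero mean
severity tends to be lower (better) under the later session.  The
familywise error rate is controlled across all six comparisons, and the
global decision is compatible with the per-row ones.

The same analyses are available from the shell:

```sh
nparrm fixtures --outdir fixtures
nparrm test --input fixtures/severity_trial_synthetic.csv \
            --subject-column subject --contrast tukey --method mctp ats2
nparrm simulate --scenario scenario.yaml --methods ats2,mctp --out rates.csv
```

See `examples/` for short narrative scripts covering effects estimation,
trial analysis, type-I error simulation and the missingness mechanisms.

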