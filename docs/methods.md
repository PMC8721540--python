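# Methods

## Model and estimands

Data are `n` i.i.d. subject vectors observed under `d` repeated
conditions; each cell carries an observation indicator `λ_ik`, and all
estimators use every observed cell ("all-available-case" analysis).  The
marginal distributions `F_i` are taken in normalized form — the average of
the left- and right-continuous CDF versions — so that ties are handled
without further assumptions and the same machinery covers metric,
ordinal and binary outcomes.  Validity of the inference rests on the
missing-completely-at-random assumption; the simulation harness exists
partly to probe robustness under two missing-at-random mechanisms.

The estimand is the vector of unweighted relative effects
`p_i = ∫ G dF_i` with `G` the equally weighted mixture of the `d`
marginals.  The package also computes the weighted effects
`r_i = ∫ H_N dF_i` (reference weighted by observed counts, estimated from
pooled mid-ranks) but uses them only descriptively and in the comparator
tests: since `H_N` changes with the missingness pattern, `r` is not a
model constant and confidence intervals for it are not meaningful.
Hypotheses are `H₀: Cp = 0` for a user-chosen contrast matrix `C` with
zero row sums; this is a nonparametric Behrens–Fisher formulation — the
marginals may differ in shape and spread under the null.

Subjects with *no* observed condition are retained in `n` by default:
the model counts i.i.d. subject vectors, and such subjects enter the
`√n` scaling and the `n − 1` covariance divisor with exactly zero
influence terms.  `RMDataset.drop_all_missing_subjects` (and the CLI flag
`--drop-all-missing`) removes them for users who prefer the reduced
count; with contrast-based inference the difference is a uniform rescaling
of order `n_missing/n`.

## Estimators

`p̂_i` plugs the per-condition normalized ecdfs into the integral
representation.  The default path evaluates each ecdf by binary search on
the sorted observed values (O(N log N) overall); a literal O(N²) sum of
count-function terms is kept as an independent reference implementation
and the equality of the two paths is asserted permanently in the test
suite.  Ties are resolved exclusively through the normalized count
function `c(u) = 0, ½, 1`; comparisons are exact floating-point equality,
which is the right semantics for the ordinal/integer data the method
targets (for metric data, exact ties occur with probability zero anyway).

The covariance of `√n (p̂ − p)` is estimated from estimated influence
functions: for each subject a vector `Ψ̂_k` (the observable surrogate of
its asymptotic influence) and its estimated expectation `β̂_k` are formed,
and `V̂_n = (1/(n−1)) Σ_k (Ψ̂_k − β̂_k)(Ψ̂_k − β̂_k)′`.  Being a sum of outer
products this is positive semidefinite by construction, and it is
consistent under arbitrary fixed alternatives — both properties the
classical rank-based estimator for the weighted effects lacks under
missingness (the test suite exhibits a small dataset on which that
estimator has a negative eigenvalue).  Terms multiplied by a zero
indicator are defined as zero without ever evaluating an ecdf at a
missing cell.  The centering identity (columns of `Ψ̂ − β̂` sum to zero)
holds exactly and is tested at 1e-10.

## Tests

* **WTS**: `Q_n = n p̂′C′[C V̂ C′]⁺ C p̂` with a χ² reference on
  `rank(C V̂ C′)` degrees of freedom.  Matrix ranks and pseudoinverses cut
  singular values below 1e-10 of the largest.  Included for completeness;
  liberal at small `n`.
* **ATS version 1**: the trace-normalized quadratic form in the projection
  `M = C′[CC′]⁺C`, referred to χ² with the Box-matched real-valued degrees
  of freedom `f̂ = tr(MV̂)²/tr(MV̂MV̂)`.  The χ² form is implemented as the
  primary definition; the F-calibrated variant is exactly what version 2
  provides, and the identity `ATS2 = ATS1 / f̂` is asserted on every run.
* **ATS version 2**: `n p̂′Mp̂ / tr(MV̂)` against `F(f̂, (n−1)f̂)`
  (Greenhouse–Geisser style second moment matching); the most accurate
  small-sample global test in the bundled studies.
* **MCTP**: per-contrast statistics `T_ℓ`, joint reference distribution
  multivariate t with `n − 1` degrees of freedom (default) or multivariate
  normal, correlation matrix `R̂ = D̂^{-1/2} C V̂ C′ D̂^{-1/2}`.  Simultaneous
  confidence intervals use the two-sided equicoordinate quantile; adjusted
  p-values are single-step max-T probabilities `1 − P(max_m |T_m| ≤ |t_ℓ|)`
  under the same reference distribution, which makes them compatible with
  the intervals by construction.  Contrasts with zero estimated variance
  are reported as NaN, excluded from the max, and flagged with a warning.
* **Comparators for the distribution-level null `CF = 0`**: the WTS/ATS
  formulas applied to the weighted effects with the classical rank
  covariance (`wts_weighted`, `ats_weighted`; labelled `wts_F_domhof` /
  `ats_F_domhof` in study output).

### Numerical quantile computation

Rectangle probabilities `P(max|T| < z)` come from scipy's multivariate
normal / multivariate t CDFs (quasi-Monte-Carlo integration; the t version
is seeded explicitly, so quantiles and p-values are reproducible given the
seed argument).  The equicoordinate quantile solves the monotone equation
by Brent root-finding on `[~0, 15]` with `xtol = 1e-5`; overall accuracy
is about 1e-4 on the probability scale, i.e. roughly 1e-3 on quantiles
near 2.  Estimated correlation matrices that are numerically singular
(e.g. perfectly correlated contrasts) receive a 1e-8 ridge before
integration, perturbing probabilities at the 1e-8 level.  All tests are
two-sided; one-sided variants are deliberately not offered.

## Simulation harness

`generate` draws latent `N(μ, Σ)` vectors, optionally exponentiates them
componentwise (log-normal), and rounds to integers (ties to even) — i.e.
discretization happens before missingness is imposed, and the mechanisms
act on the final observed values.  Six covariance patterns are bundled:
compound symmetry 0.5 in d = 3 and d = 4, and four heteroscedastic
matrices with mixed or autoregressive-like correlation.  Shift
alternatives come in three families (`last`, `last-two`, and the linear
trend `(0, 1, 2, 3)·δ`; a `trend_scale` option rescales the trend
coefficients for sensitivity checks).

Missingness mechanisms:

* **MCAR** — each cell observed independently with probability `1 − r`;
  fully missing rows can occur and are retained.
* **MAR(1)** — conditions are paired `(1,2), (3,4), …`; the second pair
  member is deleted with probability 30% when the first lies within one
  standard deviation of its center and 10% outside.  In simulations the
  true moments of the generating marginal are used for the bands; on
  external data the empirical mean/SD of the observed anchor values are
  the default.  Values exactly on the band edge count as the middle band.
  For odd `d` the default pairing leaves the last condition fully
  observed; a custom pairing map can be supplied.
* **MAR(2)** — the second pair member is deleted with probability 10%
  only when the anchor lies strictly above its observed median.

`run_study` composes generate → mechanism → handling (all-available /
complete-case / median imputation, the median of an even count being the
midpoint of the central order statistics) → tests, with rejection at
`p ≤ α`.  Replicates on which an estimator is undefined (no complete case
left, an emptied condition, degenerate covariance) are counted as
failures and excluded from that method's denominator, never as
rejections.  All randomness derives from `(seed, replicate index, stream)`
triples fed to numpy's `default_rng`, so studies are exactly reproducible
and replicates are independent streams; the MCTP's integration seed is a
further derived stream.  Inside studies the MCTP computes only the global
max-T p-value (one CDF evaluation) — provably the same rejection decision
as the full procedure — which keeps a 2,000-replicate study with MCTP
around a minute on one core; ATS/WTS-only studies take seconds.

Default study sizes are 2,000 replicates — large enough that a true 5%
level is estimated with ±0.49% Monte-Carlo standard error and the binomial
3·SE acceptance band is [0.035, 0.065] — with larger runs available as a
configuration choice.

## Synthetic severity trial

The bundled `synthetic_severity_trial` emulates the *shape* of a
four-session ordinal headache-severity study: 135 subjects, scores 0–20,
a mild improve-then-rebound trend, and a fixed, mostly monotone dropout
table (33 complete cases, two subjects never observed).  Values come from
a latent AR(1)-correlated normal (ρ = 0.7) pushed through an exponential
map and clipped, giving the right-skewed score distribution typical of
severity scales; which subject gets which missingness pattern is
randomized by the seed, independently of the values.  It is a synthetic
stand-in: passing analyses on it demonstrate the pipeline's behaviour on
realistically shaped data, not agreement with any real trial's numbers.
Real data in the same wide CSV layout can be analysed identically via
`read_wide` or the CLI.

## Known limitations

* Validity is proven under MCAR; MAR robustness is empirical only.
* No resampling/bootstrap calibration of the MCTP (the small-sample
  multivariate-t approximation can be slightly liberal in extreme
  scenarios: very small `n`, high correlation, 30% missingness).
* Between-subject factors, clustered designs and long-format inputs with
  per-visit covariates are out of scope; the layout is one row per
  subject, one column per condition.
* The weighted-effect comparator requires at least two observations per
  condition and positive pair overlap counts; it may legitimately fail on
  sparse patterns (reported as estimation errors, and as failures inside
  studies).
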