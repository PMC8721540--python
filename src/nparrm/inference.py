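"""Global tests and the multiple contrast test procedure (MCTP).

Given a contrast matrix ``C`` the null hypothesis of no treatment effect,
``C p = 0``, can be tested globally with

* the Wald-type statistic (WTS) ``Q_n = n p_hat' C' [C V_hat C']^+ C p_hat``
  against a chi-square with ``rank(C V_hat C')`` degrees of freedom —
  asymptotically exact but markedly liberal at small ``n``;
* two ANOVA-type statistics (ATS) that replace the pseudoinverse weighting
  with the projection ``M = C'[CC']^+ C`` and calibrate the quadratic form
  ``n p_hat' M p_hat`` by Box/Greenhouse-Geisser moment matching: version 1
  scales it to a chi-square with ``f = tr(M V)^2 / tr(MVMV)`` degrees of
  freedom, version 2 refers ``n p_hat' M p_hat / tr(M V)`` to an
  ``F(f, (n-1) f)`` distribution;

or — recommended in practice — with the multiple contrast test procedure,
which tests every row ``c_l' p = 0`` simultaneously via the statistics
``T_l = sqrt(n) c_l' p_hat / sqrt(c_l' V_hat c_l)``, accounts for their
correlation through the equicoordinate quantile of a multivariate normal
or multivariate t(n-1) distribution with estimated correlation matrix
``R_hat``, and yields compatible simultaneous confidence intervals and
single-step max-T adjusted p-values.

All tests operate on the unweighted effects with the PSD covariance
estimator; the comparator tests for the distribution-level hypothesis
``C F = 0`` (weighted effects with the classical rank covariance) are
exposed as :func:`wts_weighted` and :func:`ats_weighted`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from .covariance import CovarianceEstimate, covariance_domhof, covariance_psd
from .data_model import ContrastSpec, RMDataset
from .effects import unweighted_effects, weighted_effects
from .errors import DegenerateTestError, EstimationError, ValidationError

__all__ = [
    "QuadraticTestResult",
    "MCTPResult",
    "wts",
    "ats1",
    "ats2",
    "wts_weighted",
    "ats_weighted",
    "equicoordinate_quantile",
    "mctp",
]

_RANK_RTOL = 1e-10


@dataclass
class QuadraticTestResult:
    """Outcome of a quadratic global test (WTS or ATS)."""

    statistic: float
    df1: float
    df2: float  # inf for chi-square references
    p_value: float
    method: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ref = (f"chi2({self.df1:.3g})" if np.isinf(self.df2)
               else f"F({self.df1:.3g}, {self.df2:.3g})")
        return (f"{self.method}: statistic={self.statistic:.4f}, {ref}, "
                f"p={self.p_value:.4g}")


@dataclass
class MCTPResult:
    """Simultaneous inference over the rows of a contrast matrix.

    ``estimates[l] = c_l' p_hat`` with the simultaneous confidence interval
    ``estimates[l] -/+ quantile * sqrt(c_l' V_hat c_l / n)``; ``p_adjusted``
    are single-step max-T adjusted p-values, compatible with the intervals
    (an interval excludes 0 exactly when the adjusted p-value is below
    alpha, up to quantile-solver tolerance).  Contrasts with zero estimated
    variance are reported as NaN and excluded from the maximum.
    """

    estimates: np.ndarray
    T: np.ndarray
    sci_lower: np.ndarray
    sci_upper: np.ndarray
    p_adjusted: np.ndarray
    global_T0: float
    p_global: float
    quantile: float
    R_hat: np.ndarray
    approx: str
    alpha: float
    n: int
    row_labels: list[str] = field(default_factory=list)

    @property
    def reject_global(self) -> bool:
        return bool(self.global_T0 >= self.quantile)


def _as_matrix(V) -> np.ndarray:
    return V.V if isinstance(V, CovarianceEstimate) else np.asarray(V, dtype=float)


def _as_contrast(C) -> ContrastSpec:
    return C if isinstance(C, ContrastSpec) else ContrastSpec(np.asarray(C, dtype=float))


# ---------------------------------------------------------------------------
# quadratic tests
# ---------------------------------------------------------------------------

def wts(p_hat, V, C, n: int, *, method: str = "wts") -> QuadraticTestResult:
    """Wald-type statistic for ``C p = 0`` with chi-square reference.

    The degrees of freedom equal the rank of ``C V_hat C'`` (singular values
    above ``1e-10`` of the largest); a zero-rank matrix means no direction
    of the contrast space carries variance and raises a degenerate-test
    error.
    """
    spec = _as_contrast(C)
    V = _as_matrix(V)
    p_hat = np.asarray(p_hat, dtype=float)
    CVC = spec.C @ V @ spec.C.T
    sv = np.linalg.svd(CVC, compute_uv=False)
    f = int((sv > _RANK_RTOL * max(sv.max(initial=0.0), np.finfo(float).tiny)).sum())
    if f == 0:
        raise DegenerateTestError("contrast covariance C V C' has rank 0")
    Cp = spec.C @ p_hat
    stat = float(n * Cp @ np.linalg.pinv(CVC, rcond=_RANK_RTOL) @ Cp)
    stat = max(stat, 0.0)
    return QuadraticTestResult(stat, float(f), np.inf,
                               float(stats.chi2.sf(stat, f)), method)


def _ats_traces(M: np.ndarray, V: np.ndarray) -> tuple[float, float]:
    MV = M @ V
    t1 = float(np.trace(MV))
    t2 = float(np.trace(MV @ MV))
    if t1 <= 0:
        raise DegenerateTestError("tr(M V_hat) <= 0: no variance in the contrast space")
    return t1, t2


def ats1(p_hat, V, C, n: int, *, method: str = "ats1") -> QuadraticTestResult:
    """ANOVA-type statistic, version 1: scaled chi-square (Box) approximation.

    ``A_n = n tr(MV) / tr(MVMV) * p_hat' M p_hat`` referred to a chi-square
    with the real-valued degrees of freedom ``f = tr(MV)^2 / tr(MVMV)``.
    """
    spec = _as_contrast(C)
    V = _as_matrix(V)
    p_hat = np.asarray(p_hat, dtype=float)
    t1, t2 = _ats_traces(spec.M, V)
    quad = float(p_hat @ spec.M @ p_hat)
    stat = max(n * t1 / t2 * quad, 0.0)
    f = t1 * t1 / t2
    return QuadraticTestResult(stat, f, np.inf, float(stats.chi2.sf(stat, f)), method)


def ats2(p_hat, V, C, n: int, *, method: str = "ats2") -> QuadraticTestResult:
    """ANOVA-type statistic, version 2: Greenhouse-Geisser F approximation.

    ``A_{n,2} = n p_hat' M p_hat / tr(MV)`` referred to an F distribution
    with ``(f, (n-1) f)`` degrees of freedom, ``f`` as in :func:`ats1`; the
    two versions satisfy ``A_{n,2} = A_n / f`` identically.
    """
    if n < 2:
        raise EstimationError("ats2 needs n >= 2")
    spec = _as_contrast(C)
    V = _as_matrix(V)
    p_hat = np.asarray(p_hat, dtype=float)
    t1, t2 = _ats_traces(spec.M, V)
    quad = float(p_hat @ spec.M @ p_hat)
    stat = max(n * quad / t1, 0.0)
    f = t1 * t1 / t2
    return QuadraticTestResult(stat, f, (n - 1) * f,
                               float(stats.f.sf(stat, f, (n - 1) * f)), method)


def wts_weighted(ds: RMDataset, C) -> QuadraticTestResult:
    """Wald-type comparator for the distribution-level hypothesis ``C F = 0``.

    Uses the weighted effects ``r_hat`` with the classical (not necessarily
    PSD) rank covariance estimator.
    """
    r_hat = weighted_effects(ds)
    V = covariance_domhof(ds)
    return wts(r_hat, V, C, ds.n_subjects, method="wts_F_domhof")


def ats_weighted(ds: RMDataset, C) -> QuadraticTestResult:
    """ANOVA-type comparator for ``C F = 0`` (weighted effects, rank covariance)."""
    r_hat = weighted_effects(ds)
    V = covariance_domhof(ds)
    return ats1(r_hat, V, C, ds.n_subjects, method="ats_F_domhof")


# ---------------------------------------------------------------------------
# multiple contrast test procedure
# ---------------------------------------------------------------------------

def _prepare_correlation(R: np.ndarray) -> np.ndarray:
    R = np.atleast_2d(np.asarray(R, dtype=float))
    R = (R + R.T) / 2.0
    if np.abs(np.diag(R) - 1.0).max() > 1e-6:
        raise ValidationError("correlation matrix must have unit diagonal")
    eig = np.linalg.eigvalsh(R)
    if eig.min() < -1e-8:
        raise ValidationError("correlation matrix is not positive semidefinite")
    if eig.min() < 1e-10:
        # ridge for numerically singular R (e.g. perfectly correlated
        # contrasts); perturbs rectangle probabilities at the 1e-8 level
        q = R.shape[0]
        R = (1.0 - 1e-8) * R + 1e-8 * np.eye(q)
    return R


def _rectangle_prob(z: float, R: np.ndarray, df, seed: int) -> float:
    """P(max_l |T_l| < z) under N(0, R) (df=None/inf) or multivariate t_df."""
    q = R.shape[0]
    if z <= 0:
        return 0.0
    upper = np.full(q, float(z))
    if df is None or np.isinf(df):
        return float(stats.multivariate_normal.cdf(
            upper, mean=np.zeros(q), cov=R, lower_limit=-upper,
            allow_singular=True))
    mvt = stats.multivariate_t(loc=np.zeros(q), shape=R, df=float(df))
    return float(mvt.cdf(upper, lower_limit=-upper, maxpts=20000 * q,
                         random_state=np.random.default_rng(seed)))


def equicoordinate_quantile(R, alpha: float, df=None, seed: int = 42) -> float:
    """Two-sided ``(1 - alpha)`` equicoordinate quantile.

    Returns the common threshold ``z`` with
    ``P(|T_1| < z, ..., |T_q| < z) = 1 - alpha`` for ``T ~ N(0, R)``
    (``df=None`` or ``inf``) or a central multivariate t with ``df``
    degrees of freedom and correlation ``R``.  Solved by Brent root-finding
    on the monotone rectangle probability; the probability itself is
    evaluated by (quasi-)Monte-Carlo integration seeded by ``seed``, so the
    result is reproducible and accurate to about 1e-4 on the probability
    scale.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError("alpha must be in (0, 1)")
    if df is not None and not np.isinf(df) and df < 1:
        raise ValidationError("df must be >= 1 (or None/inf for the normal)")
    R = _prepare_correlation(R)

    def g(z: float) -> float:
        return _rectangle_prob(z, R, df, seed) - (1.0 - alpha)

    hi = 15.0
    if g(hi) < 0:  # pragma: no cover - extreme alpha/df corner
        hi = 80.0
    return float(brentq(g, 1e-9, hi, xtol=1e-5))


def mctp(ds: RMDataset, C, alpha: float = 0.05, approx: str = "mvt",
         seed: int = 42, eff=None, V: CovarianceEstimate | None = None) -> MCTPResult:
    """Multiple contrast test procedure with simultaneous confidence intervals.

    Estimates every contrast ``c_l' p``, forms the studentized statistics
    ``T_l``, estimates their correlation ``R_hat = D^{-1/2} C V_hat C'
    D^{-1/2}`` and performs joint max-|T| inference: simultaneous
    ``(1 - alpha)`` confidence intervals, single-step adjusted p-values and
    the global max-T test.  ``approx="mvt"`` (default, recommended for
    small samples) uses a central multivariate t with ``n - 1`` degrees of
    freedom, ``"mvn"`` the multivariate normal.
    """
    if approx not in ("mvt", "mvn"):
        raise ValidationError("approx must be 'mvt' or 'mvn'")
    spec = _as_contrast(C)
    n = ds.n_subjects
    if n < 2:
        raise EstimationError("mctp needs n >= 2 subjects")
    if eff is None:
        eff = unweighted_effects(ds)
    if V is None:
        V = covariance_psd(ds, eff)
    Vm = _as_matrix(V)
    est = spec.C @ eff.p_hat
    CVC = spec.C @ Vm @ spec.C.T
    var_c = np.diag(CVC).copy()
    tiny = 1e-12 * max(1.0, float(var_c.max(initial=0.0)))
    ok = var_c > tiny
    if not ok.any():
        raise EstimationError("all contrasts have zero estimated variance")
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} contrast(s) with zero estimated variance "
            "reported as NaN and excluded from the max-T statistic",
            RuntimeWarning, stacklevel=2)

    T = np.full(spec.q, np.nan)
    T[ok] = np.sqrt(n) * est[ok] / np.sqrt(var_c[ok])
    sub = np.ix_(ok, ok)
    Dinv = 1.0 / np.sqrt(var_c[ok])
    R_sub = CVC[sub] * np.outer(Dinv, Dinv)
    np.fill_diagonal(R_sub, 1.0)
    R_hat = np.full((spec.q, spec.q), np.nan)
    R_hat[sub] = R_sub

    df = n - 1 if approx == "mvt" else None
    Rp = _prepare_correlation(R_sub)
    z = equicoordinate_quantile(Rp, alpha, df=df, seed=seed)

    half = np.full(spec.q, np.nan)
    half[ok] = z * np.sqrt(var_c[ok] / n)
    p_adj = np.full(spec.q, np.nan)
    for l in np.nonzero(ok)[0]:
        p_adj[l] = 1.0 - _rectangle_prob(abs(T[l]), Rp, df, seed)
    T0 = float(np.nanmax(np.abs(T)))
    p_global = 1.0 - _rectangle_prob(T0, Rp, df, seed)
    return MCTPResult(
        estimates=est, T=T, sci_lower=est - half, sci_upper=est + half,
        p_adjusted=np.clip(p_adj, 0.0, 1.0), global_T0=T0,
        p_global=float(np.clip(p_global, 0.0, 1.0)), quantile=z,
        R_hat=R_hat, approx=approx, alpha=alpha, n=n,
        row_labels=list(spec.row_labels),
    )


def mctp_global_pvalue(ds: RMDataset, C, approx: str = "mvt",
                       seed: int = 42) -> float:
    """Global max-T p-value only (one rectangle-probability evaluation).

    Lightweight path for simulation studies: decides rejection identically
    to :func:`mctp` (``p <= alpha`` iff ``T0 >= quantile``) without solving
    for the quantile or per-contrast quantities.
    """
    spec = _as_contrast(C)
    eff = unweighted_effects(ds)
    V = covariance_psd(ds, eff)
    est = spec.C @ eff.p_hat
    CVC = spec.C @ V.V @ spec.C.T
    var_c = np.diag(CVC)
    tiny = 1e-12 * max(1.0, float(var_c.max(initial=0.0)))
    ok = var_c > tiny
    if not ok.any():
        raise EstimationError("all contrasts have zero estimated variance")
    T = np.sqrt(ds.n_subjects) * est[ok] / np.sqrt(var_c[ok])
    Dinv = 1.0 / np.sqrt(var_c[ok])
    R = CVC[np.ix_(ok, ok)] * np.outer(Dinv, Dinv)
    np.fill_diagonal(R, 1.0)
    df = ds.n_subjects - 1 if approx == "mvt" else None
    T0 = float(np.abs(T).max())
    return float(np.clip(1.0 - _rectangle_prob(T0, _prepare_correlation(R), df, seed),
                         0.0, 1.0))
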