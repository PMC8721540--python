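"""Covariance estimation for the relative-effect estimators.

Two estimators of the covariance matrix of ``sqrt(n) (p_hat - p)`` (resp.
``sqrt(n) r_hat``) are provided:

* :func:`covariance_psd` — an influence-function-based estimator for the
  unweighted effects that is positive semidefinite by construction (it is
  a sum of outer products) and consistent under arbitrary fixed
  alternatives.  This is the estimator all confidence intervals and tests
  for hypotheses in ``p`` are built on.
* :func:`covariance_domhof` — the classical rank-based estimator for the
  weighted effects.  With missing values it is *not* guaranteed positive
  semidefinite, which can render downstream variance estimates of
  contrasts negative; it is retained as the comparator used by the
  hypothesis-in-``F`` Wald- and ANOVA-type tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import RMDataset
from .effects import EffectEstimates, _condition_ecdfs, midranks, unweighted_effects
from .errors import EstimationError

__all__ = [
    "CovarianceEstimate",
    "InfluenceTerms",
    "influence_terms",
    "covariance_psd",
    "covariance_domhof",
]


@dataclass
class CovarianceEstimate:
    """A ``d x d`` covariance matrix estimate with provenance.

    ``kind`` is ``"psd_unweighted"`` for the influence-based estimator of
    the unweighted effects or ``"domhof_weighted"`` for the rank-based
    comparator.  ``psd_checked`` records whether the smallest eigenvalue
    clears ``-1e-10 * max(1, largest eigenvalue)``.
    """

    V: np.ndarray
    kind: str
    psd_checked: bool
    min_eigenvalue: float


@dataclass
class InfluenceTerms:
    """Estimated influence decomposition of ``sqrt(n)(p_hat - p)``.

    ``psi_hat[k, i]`` is the observable surrogate of the influence variable
    of subject ``k`` on effect ``i``; ``beta_hat[k, i]`` is its estimated
    expectation.  Rows of subjects with no observation at all are zero in
    both matrices: such subjects carry no information but still count
    toward ``n``.
    """

    psi_hat: np.ndarray
    beta_hat: np.ndarray


def _check_psd(V: np.ndarray) -> tuple[bool, float]:
    eig = np.linalg.eigvalsh((V + V.T) / 2.0)
    tol = -1e-10 * max(1.0, float(eig.max(initial=0.0)))
    return bool(eig.min() >= tol), float(eig.min())


def influence_terms(ds: RMDataset, eff: EffectEstimates) -> InfluenceTerms:
    """Per-subject influence surrogates ``psi_hat`` and their centerings ``beta_hat``.

    For condition ``i`` and subject ``k``::

        psi_hat[k,i] = (n lam_ik / lam_i) (G_hat(X_ik) - F_hat_i(X_ik)/d)
                       - (1/d) sum_{s != i} (n lam_sk / lam_s) F_hat_i(X_sk)
        beta_hat[k,i] = (n lam_ik / lam_i) (p_hat_i - 1/(2d))
                       - (1/d) sum_{s != i} (n lam_sk / lam_s) pairwise[i,s]

    Any term multiplied by a zero indicator contributes 0 without the ecdf
    ever being evaluated at a missing cell.  The columns of
    ``psi_hat - beta_hat`` sum to zero exactly.
    """
    n, d = ds.n_subjects, ds.n_conditions
    lam = ds.lam.astype(float)
    lam_i = ds.lam_per_condition.astype(float)
    if (lam_i < 1).any():
        raise EstimationError("every condition needs at least one observation")
    fns = _condition_ecdfs(ds)
    vals = np.where(ds.lam == 1, ds.values, 0.0)  # placeholder at missing cells

    # F[i][k, s] = F_hat_i(X_sk) where observed, 0 where missing
    F = np.zeros((d, n, d))
    for i in range(d):
        F[i] = np.where(ds.lam == 1, fns[i](vals), 0.0)
    G = F.mean(axis=0)  # G_hat(X_sk) masked the same way

    w = n * lam / lam_i  # n lam_sk / lam_s, (n x d)
    psi = np.zeros((n, d))
    beta = np.zeros((n, d))
    for i in range(d):
        own = w[:, i] * (G[:, i] - F[i][:, i] / d)
        cross = (w * F[i]).sum(axis=1) - w[:, i] * F[i][:, i]
        psi[:, i] = own - cross / d
        own_b = w[:, i] * (eff.p_hat[i] - 0.5 / d)
        cross_b = w @ eff.pairwise[i] - w[:, i] * 0.5
        beta[:, i] = own_b - cross_b / d
    return InfluenceTerms(psi_hat=psi, beta_hat=beta)


def covariance_psd(ds: RMDataset, eff: EffectEstimates | None = None) -> CovarianceEstimate:
    """Positive-semidefinite estimator of ``Cov(sqrt(n)(p_hat - p))``.

    ``V_hat = (1/(n-1)) sum_k (psi_k - beta_k)(psi_k - beta_k)'`` — a sum of
    outer products, hence PSD by construction, and consistent as the number
    of observations per condition grows.  The divisor is ``n - 1`` exactly,
    also when fully missing subjects are retained in ``n``.
    """
    if ds.n_subjects < 2:
        raise EstimationError("covariance estimation needs n >= 2 subjects")
    if eff is None:
        eff = unweighted_effects(ds)
    terms = influence_terms(ds, eff)
    D = terms.psi_hat - terms.beta_hat
    V = D.T @ D / (ds.n_subjects - 1)
    V = (V + V.T) / 2.0
    ok, min_eig = _check_psd(V)
    return CovarianceEstimate(V=V, kind="psd_unweighted", psd_checked=ok,
                              min_eigenvalue=min_eig)


def covariance_domhof(ds: RMDataset) -> CovarianceEstimate:
    """Rank-based covariance estimator for the weighted effects ``sqrt(n) r_hat``.

    Diagonal entries are ``n / (N^2 lam_i (lam_i - 1)) sum_k lam_ik
    (R_ik - Rbar_i)^2``; off-diagonal entries use the divisor
    ``K(i, i') = (lam_i - 1)(lam_i' - 1) + Lambda(i, i') - 1`` with
    ``Lambda`` the number of subjects observed under both conditions.  Not
    guaranteed PSD under missingness; ``psd_checked`` reports the finding
    (with a warning when it fails) rather than enforcing it.
    """
    n, d = ds.n_subjects, ds.n_conditions
    N = ds.n_total_obs
    lam = ds.lam.astype(float)
    lam_i = ds.lam_per_condition.astype(float)
    if (lam_i < 2).any():
        raise EstimationError("the weighted-effect covariance needs >= 2 observations per condition")
    R = midranks(ds)
    rbar = R.sum(axis=0) / lam_i
    Rc = np.where(ds.lam == 1, R - rbar, 0.0)  # centered ranks, 0 at missing
    V = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            if i == j:
                ss = float((lam[:, i] * Rc[:, i] ** 2).sum())
                V[i, i] = n * ss / (N ** 2 * lam_i[i] * (lam_i[i] - 1.0))
            else:
                Lam = float((lam[:, i] * lam[:, j]).sum())
                K = (lam_i[i] - 1.0) * (lam_i[j] - 1.0) + Lam - 1.0
                if K <= 0:
                    raise EstimationError(
                        f"degenerate overlap between conditions {i + 1} and {j + 1}"
                    )
                cross = float((lam[:, i] * lam[:, j] * Rc[:, i] * Rc[:, j]).sum())
                V[i, j] = V[j, i] = n * cross / (N ** 2 * K)
    ok, min_eig = _check_psd(V)
    if not ok:
        warnings.warn(
            "weighted-effect covariance estimate is not positive semidefinite "
            f"(min eigenvalue {min_eig:.3e})", RuntimeWarning, stacklevel=2)
    return CovarianceEstimate(V=V, kind="domhof_weighted", psd_checked=ok,
                              min_eigenvalue=min_eig)
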