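"""Relative-effect estimation from all-available data.

The treatment effect of condition ``i`` is expressed on the probability
scale: the unweighted relative effect ``p_i = P(Z < X_i) + 0.5 P(Z = X_i)``
compares the marginal distribution ``F_i`` with the unweighted mean
distribution ``G = (1/d) sum_s F_s`` of all conditions.  ``p_i = 1/2``
means values from condition ``i`` tend neither to be smaller nor larger
than a value drawn from the pooled reference.  Because ``G`` is a model
constant, ``p`` is a valid inference target even when the amount of
missingness differs between conditions — unlike the weighted effects
``r_i``, whose reference distribution weights each condition by its number
of observed values and therefore changes with the missingness pattern.

Ties are handled throughout by the normalized count function
``c(u) = 0, 1/2, 1`` for ``u < 0, = 0, > 0`` (equivalently the average of
the left- and right-continuous empirical distribution functions), which is
what makes the estimators applicable to metric, ordinal and binary data in
a unified way and yields mid-ranks for tied observations.

Estimators use every observed cell (all-available-case analysis): the
empirical distribution function of condition ``i`` averages the count
function over the ``lam_i`` observed values of that condition only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_model import RMDataset
from .errors import EstimationError, ValidationError

__all__ = [
    "EffectEstimates",
    "count_function",
    "ecdf_eval",
    "midranks",
    "weighted_effects",
    "unweighted_effects",
    "unweighted_effects_bruteforce",
]


@dataclass
class EffectEstimates:
    """Point estimates of the relative effects of one dataset.

    Attributes
    ----------
    p_hat
        Unweighted relative effects ``p_hat_i = ∫ G_hat dF_hat_i`` (d-vector).
    r_hat
        Weighted relative effects ``r_hat_i = (mean rank_i - 1/2) / N``.
    pairwise
        ``d x d`` matrix with entry ``(i, s) = ∫ F_hat_i dF_hat_s``, the
        estimated probability that a value from condition ``s`` exceeds one
        from condition ``i`` (ties counted half).  Diagonal is 1/2 and
        ``pairwise[i, s] + pairwise[s, i] = 1``.
    ranks
        ``n x d`` mid-ranks of each observed cell among all N observed
        values; 0 where missing.
    """

    p_hat: np.ndarray
    r_hat: np.ndarray
    pairwise: np.ndarray
    ranks: np.ndarray


def count_function(u):
    """Normalized count function ``c(u)``: 0, 1/2, 1 for ``u <, =, > 0``.

    Accepts scalars or arrays; raises on non-finite input.
    """
    arr = np.asarray(u, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("count function requires finite arguments")
    out = 0.5 * (np.sign(arr) + 1.0)
    return out if arr.ndim else float(out)


class _NormalizedECDF:
    """Normalized empirical distribution function of one condition's observed values.

    Evaluates ``F_hat_i(x) = (#{obs < x} + 0.5 #{obs = x}) / lam_i`` in
    O(log lam_i) per point via binary search on the sorted observations.
    """

    def __init__(self, observed: np.ndarray):
        if observed.size == 0:
            raise EstimationError("cannot build an ecdf from zero observations")
        self._sorted = np.sort(observed)
        self._n = observed.size

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = np.searchsorted(self._sorted, x, side="left")
        hi = np.searchsorted(self._sorted, x, side="right")
        return (lo + hi) / (2.0 * self._n)


def _condition_ecdfs(ds: RMDataset) -> list[_NormalizedECDF]:
    fns = []
    for i in range(ds.n_conditions):
        obs = ds.values[ds.lam[:, i] == 1, i]
        if obs.size == 0:
            raise EstimationError(
                f"condition {ds.condition_names[i]} has no observed value"
            )
        fns.append(_NormalizedECDF(obs))
    return fns


def ecdf_eval(ds: RMDataset, i: int, x) -> np.ndarray:
    """Evaluate the normalized all-available ecdf of condition ``i`` at points ``x``."""
    obs = ds.values[ds.lam[:, i] == 1, i]
    if obs.size == 0:
        raise EstimationError(
            f"condition {ds.condition_names[i]} has no observed value"
        )
    return _NormalizedECDF(obs)(x)


def midranks(ds: RMDataset) -> np.ndarray:
    """Mid-ranks of every observed cell among all ``N`` observed values.

    Equivalent to ``R_ik = N * H_hat_N(X_ik) + 1/2`` with ``H_hat_N`` the
    weighted mean ecdf; missing cells get rank 0 by convention.  The sum of
    all nonzero ranks is ``N (N + 1) / 2``.
    """
    obs = ds.lam == 1
    pooled = ds.values[obs]
    if pooled.size == 0:
        raise EstimationError("no observed values to rank")
    ranks = np.zeros_like(ds.values)
    ranks[obs] = rankdata(pooled, method="average")
    return ranks


def weighted_effects(ds: RMDataset) -> np.ndarray:
    """Weighted relative effects ``r_hat_i = (Rbar_i - 1/2) / N`` from pooled mid-ranks."""
    ranks = midranks(ds)
    lam_i = ds.lam_per_condition
    rbar = ranks.sum(axis=0) / lam_i
    return (rbar - 0.5) / ds.n_total_obs


def _pairwise_matrix(ds: RMDataset) -> np.ndarray:
    """``pairwise[i, s] = ∫ F_hat_i dF_hat_s`` via sorted-search ecdf evaluation."""
    d = ds.n_conditions
    fns = _condition_ecdfs(ds)
    pw = np.empty((d, d))
    obs_vals = [ds.values[ds.lam[:, s] == 1, s] for s in range(d)]
    for i in range(d):
        for s in range(d):
            pw[i, s] = float(np.mean(fns[i](obs_vals[s])))
    return pw


def unweighted_effects(ds: RMDataset) -> EffectEstimates:
    """Estimate the unweighted relative effects and all companion quantities.

    ``p_hat_i`` averages the pairwise effects over the reference conditions:
    ``p_hat_i = (1/d) sum_s ∫ F_hat_s dF_hat_i``.  The default path runs in
    O(N log N) via sorted binary searches; it agrees with the literal
    quadruple sum over the count function (see
    :func:`unweighted_effects_bruteforce`) to machine precision, which the
    test suite asserts permanently.
    """
    pw = _pairwise_matrix(ds)
    p_hat = pw.mean(axis=0)  # p_hat_i = (1/d) sum_s pairwise[s, i]
    return EffectEstimates(
        p_hat=p_hat,
        r_hat=weighted_effects(ds),
        pairwise=pw,
        ranks=midranks(ds),
    )


def unweighted_effects_bruteforce(ds: RMDataset) -> np.ndarray:
    """Literal quadruple-loop evaluation of the unweighted-effect double sum.

    O(N^2) reference oracle kept independent of the fast path; used in
    tests and suitable only for small datasets.
    """
    n, d = ds.n_subjects, ds.n_conditions
    lam = ds.lam
    lam_i = ds.lam_per_condition
    if (lam_i == 0).any():
        raise EstimationError("every condition needs at least one observation")
    p_hat = np.zeros(d)
    for i in range(d):
        total = 0.0
        for k in range(n):
            if lam[k, i] == 0:
                continue
            inner = 0.0
            for s in range(d):
                acc = 0.0
                for ell in range(n):
                    if lam[ell, s] == 0:
                        continue
                    u = ds.values[k, i] - ds.values[ell, s]
                    acc += 0.0 if u < 0 else (0.5 if u == 0 else 1.0)
                inner += acc / lam_i[s]
            total += inner / d
        p_hat[i] = total / lam_i[i]
    return p_hat
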