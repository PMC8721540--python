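"""Simulation harness: data generators, missingness mechanisms, naive comparators.

The generator draws ``n`` i.i.d. ``d``-vectors from a multivariate normal
``N(mu, Sigma)`` (optionally exponentiated componentwise to a log-normal)
and discretizes by rounding to integers, producing the kind of
integer-valued, possibly skewed repeated measurements the rank methods
target.  Missingness is then imposed on the discretized values by one of

* MCAR — every cell is observed independently with probability ``1 - r``;
* MAR(1) — conditions are grouped into pairs ``{X_obs, X_miss}``; the
  miss-member is deleted with probability 10% when the observed partner
  lies in the outer thirds ``(-inf, -sigma)`` / ``(sigma, inf)`` of its
  centered scale and 30% in the middle band;
* MAR(2) — the miss-member is deleted with probability 10% when the
  observed partner lies above its observed median, never when below.

Six covariance matrices are bundled (``SIGMA["sigma1"]`` ... ``"sigma6"``),
ranging from compound symmetry to strongly heteroscedastic patterns, along
with the three shift-alternative families used for power studies.  The
study runner ties generation, missingness, a handling strategy
(all-available, complete-case, or median imputation) and the test methods
together and reports rejection proportions with Monte-Carlo standard
errors; replicates on which an estimator is undefined are counted as
failures, never as rejections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import ContrastSpec, RMDataset, tukey_contrast
from .errors import EstimationError, ValidationError
from . import inference
from .covariance import covariance_psd
from .effects import unweighted_effects

__all__ = [
    "SIGMA",
    "ScenarioConfig",
    "StudyResult",
    "alternative_mu",
    "generate",
    "apply_mcar",
    "apply_mar1",
    "apply_mar2",
    "complete_cases",
    "median_impute",
    "run_study",
]

#: The six bundled covariance matrices: compound symmetry with correlation
#: 0.5 in d=3 and d=4 (homoscedastic), plus four heteroscedastic patterns
#: with autoregressive-like or mixed correlation structure.
SIGMA: dict[str, np.ndarray] = {
    "sigma1": np.array([[1.0, 0.5, 0.5],
                        [0.5, 1.0, 0.5],
                        [0.5, 0.5, 1.0]]),
    "sigma2": np.array([[1.0, 0.5, 0.5, 0.5],
                        [0.5, 1.0, 0.5, 0.5],
                        [0.5, 0.5, 1.0, 0.5],
                        [0.5, 0.5, 0.5, 1.0]]),
    "sigma3": np.array([[1.0, 0.3, 0.6],
                        [0.3, 1.2, 0.9],
                        [0.6, 0.9, 1.5]]),
    "sigma4": np.array([[1.0, 0.2, 0.4, 0.6],
                        [0.2, 2.0, 0.7, 0.5],
                        [0.4, 0.7, 2.5, 0.6],
                        [0.6, 0.5, 0.6, 3.0]]),
    "sigma5": np.array([[1.0, 0.6, 0.36, 0.216],
                        [0.6, 1.0, 0.6, 0.36],
                        [0.36, 0.6, 1.0, 0.6],
                        [0.216, 0.36, 0.6, 1.0]]),
    "sigma6": np.array([[1.0, 0.8, 0.64, 0.512],
                        [0.8, 1.5, 0.8, 0.64],
                        [0.64, 0.8, 2.0, 0.8],
                        [0.512, 0.64, 0.8, 2.5]]),
}

_METHODS = ("wts", "ats1", "ats2", "mctp", "wts_F_domhof", "ats_F_domhof")
_HANDLINGS = ("all_available", "complete_case", "median_impute")


def alternative_mu(kind: int, delta: float, d: int = 4,
                   trend_scale: float = 1.0) -> np.ndarray:
    """Mean vectors of the three shift-alternative families.

    Kind 1: ``(0, ..., 0, delta)`` (one shifted condition); kind 2:
    ``(0, ..., delta, delta)`` (last two shifted); kind 3 (d=4): the linear
    trend ``(0, 1, 2, 3) * delta * trend_scale``.  ``trend_scale`` rescales
    the trend coefficients (default 1, i.e. coefficients exactly 0,1,2,3).
    """
    mu = np.zeros(d)
    if kind == 1:
        mu[-1] = delta
    elif kind == 2:
        mu[-2:] = delta
    elif kind == 3:
        mu = np.arange(d, dtype=float) * delta * trend_scale
    else:
        raise ValidationError("alternative kind must be 1, 2 or 3")
    return mu


@dataclass
class ScenarioConfig:
    """One simulation scenario.

    ``sigma`` may be a name (``"sigma1"`` ... ``"sigma6"``) or an explicit
    PSD matrix; ``mu`` defaults to the null (zeros).  ``missing_rate``
    applies to MCAR only (the MAR mechanisms have their group rates built
    in).  Defaults mirror a mid-sized null scenario: discretized normal,
    2,000 replicates, nominal level 5%.
    """

    distribution: str = "discretized_normal"
    d: int = 3
    n: int = 30
    sigma: object = "sigma1"
    missing_mechanism: str = "none"
    missing_rate: float = 0.1
    mu: np.ndarray | None = None
    reps: int = 2000
    alpha: float = 0.05
    seed: int = 42
    mar_pairs: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.distribution not in ("discretized_normal", "discretized_lognormal"):
            raise ValidationError(f"unknown distribution {self.distribution!r}")
        if self.missing_mechanism not in ("none", "mcar", "mar1", "mar2"):
            raise ValidationError(f"unknown mechanism {self.missing_mechanism!r}")
        if isinstance(self.sigma, str):
            if self.sigma not in SIGMA:
                raise ValidationError(f"unknown covariance name {self.sigma!r}")
            self.sigma_matrix = SIGMA[self.sigma]
        else:
            self.sigma_matrix = np.asarray(self.sigma, dtype=float)
        if self.sigma_matrix.shape != (self.d, self.d):
            raise ValidationError(
                f"sigma has shape {self.sigma_matrix.shape}, expected ({self.d}, {self.d})"
            )
        eig = np.linalg.eigvalsh((self.sigma_matrix + self.sigma_matrix.T) / 2)
        if eig.min() < -1e-10:
            raise ValidationError("sigma must be positive semidefinite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0, 1)")
        self.mu = (np.zeros(self.d) if self.mu is None
                   else np.asarray(self.mu, dtype=float))
        if self.mu.shape != (self.d,):
            raise ValidationError("mu must be a d-vector")


@dataclass
class StudyResult:
    """Rejection proportions of one scenario, per method."""

    config: ScenarioConfig
    handling: str
    rejections: dict[str, int]
    failures: dict[str, int]
    reps_completed: dict[str, int]

    @property
    def rejection_rate(self) -> dict[str, float]:
        return {m: (self.rejections[m] / self.reps_completed[m]
                    if self.reps_completed[m] else float("nan"))
                for m in self.rejections}

    @property
    def mc_se(self) -> dict[str, float]:
        out = {}
        for m, rate in self.rejection_rate.items():
            reps = self.reps_completed[m]
            out[m] = float(np.sqrt(rate * (1 - rate) / reps)) if reps else float("nan")
        return out


# ---------------------------------------------------------------------------
# generation and missingness
# ---------------------------------------------------------------------------

def _rng(seed: int, rep_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, rep_index, stream])


def generate(config: ScenarioConfig, rep_index: int = 0) -> RMDataset:
    """Draw one complete dataset for the scenario, deterministically per replicate.

    Latent vectors are ``N(mu, Sigma)``; for the log-normal they are
    exponentiated componentwise; values are then rounded to the nearest
    integer (ties to even).
    """
    rng = _rng(config.seed, rep_index, 0)
    latent = rng.multivariate_normal(config.mu, config.sigma_matrix,
                                     size=config.n, method="svd")
    if config.distribution == "discretized_lognormal":
        latent = np.exp(latent)
    values = np.rint(latent)
    return RMDataset(values, np.ones_like(values, dtype=int))


def _marginal_moments(config: ScenarioConfig) -> tuple[np.ndarray, np.ndarray]:
    """True mean and standard deviation of each (pre-discretization) marginal."""
    var = np.diag(config.sigma_matrix)
    if config.distribution == "discretized_lognormal":
        mean = np.exp(config.mu + var / 2.0)
        sd = np.sqrt((np.exp(var) - 1.0) * np.exp(2.0 * config.mu + var))
        return mean, sd
    return config.mu.copy(), np.sqrt(var)


def default_pairs(d: int) -> list[tuple[int, int]]:
    """Default (observed, missing-prone) pairing: (1,2), (3,4), ...; for odd
    ``d`` the last condition stays fully observed."""
    return [(i, i + 1) for i in range(0, d - 1, 2)]


def apply_mcar(ds: RMDataset, r: float, seed: int = 0) -> RMDataset:
    """Missing completely at random: each observed cell kept with probability ``1 - r``."""
    if not 0.0 <= r < 1.0:
        raise ValidationError("MCAR rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    keep = rng.random(ds.lam.shape) >= r
    lam = ds.lam * keep
    return RMDataset(np.where(lam == 1, ds.values, np.nan), lam,
                     list(ds.condition_names), list(ds.subject_ids))


def _apply_mar(ds: RMDataset, seed, pairs, delete_prob) -> RMDataset:
    rng = np.random.default_rng(seed)
    lam = ds.lam.copy()
    for obs, miss in pairs:
        observed = ds.lam[:, obs] == 1
        p = np.zeros(ds.n_subjects)
        p[observed] = delete_prob(ds.values[observed, obs], obs)
        drop = rng.random(ds.n_subjects) < p
        lam[:, miss] = np.where(drop, 0, lam[:, miss])
    return RMDataset(np.where(lam == 1, ds.values, np.nan), lam,
                     list(ds.condition_names), list(ds.subject_ids))


def apply_mar1(ds: RMDataset, seed: int = 0,
               pairs: list[tuple[int, int]] | None = None,
               center: np.ndarray | None = None,
               scale: np.ndarray | None = None) -> RMDataset:
    """Missing at random, three-band variant.

    Within each (observed, missing-prone) pair the missing-prone member is
    deleted with probability 30% when the observed partner lies within one
    standard deviation of its center and 10% outside that band.  ``center``
    and ``scale`` default to the empirical mean and standard deviation of
    the observed partner values; in a simulation the true moments of the
    generating model should be passed instead.  Values at exactly one
    standard deviation count as the middle band.  Subjects whose observed
    partner is itself missing are left untouched.
    """
    pairs = default_pairs(ds.n_conditions) if pairs is None else pairs

    def prob(x: np.ndarray, obs: int) -> np.ndarray:
        c = (float(np.nanmean(ds.values[ds.lam[:, obs] == 1, obs]))
             if center is None else float(np.asarray(center)[obs]))
        s = (float(np.nanstd(ds.values[ds.lam[:, obs] == 1, obs], ddof=1))
             if scale is None else float(np.asarray(scale)[obs]))
        middle = np.abs(x - c) <= s
        return np.where(middle, 0.3, 0.1)

    return _apply_mar(ds, seed, pairs, prob)


def apply_mar2(ds: RMDataset, seed: int = 0,
               pairs: list[tuple[int, int]] | None = None) -> RMDataset:
    """Missing at random, median-split variant.

    The missing-prone pair member is deleted with probability 10% when its
    observed partner lies strictly above the partner's observed median and
    never otherwise.
    """
    pairs = default_pairs(ds.n_conditions) if pairs is None else pairs

    def prob(x: np.ndarray, obs: int) -> np.ndarray:
        med = float(np.median(ds.values[ds.lam[:, obs] == 1, obs]))
        return np.where(x > med, 0.1, 0.0)

    return _apply_mar(ds, seed, pairs, prob)


# ---------------------------------------------------------------------------
# naive handling comparators
# ---------------------------------------------------------------------------

def complete_cases(ds: RMDataset) -> RMDataset:
    """Keep only subjects observed under every condition."""
    keep = (ds.lam == 1).all(axis=1)
    if not keep.any():
        raise EstimationError("no complete cases in the dataset")
    ids = [s for s, k in zip(ds.subject_ids, keep) if k] if ds.subject_ids else []
    return RMDataset(ds.values[keep], ds.lam[keep], list(ds.condition_names), ids)


def median_impute(ds: RMDataset) -> RMDataset:
    """Replace every missing cell by the median of its condition's observed values.

    With an even number of observed values the median is the midpoint of
    the two central order statistics.  All indicators are set to 1
    afterwards, so downstream methods treat the data as complete — the
    naive strategy whose inflated type-I error the simulation study
    demonstrates.
    """
    values = ds.values.copy()
    for i in range(ds.n_conditions):
        obs = ds.lam[:, i] == 1
        if not obs.any():
            raise EstimationError(
                f"condition {ds.condition_names[i]} has no observed value to impute from"
            )
        values[~obs, i] = float(np.median(values[obs, i]))
    return RMDataset(values, np.ones_like(ds.lam),
                     list(ds.condition_names), list(ds.subject_ids))


# ---------------------------------------------------------------------------
# study runner
# ---------------------------------------------------------------------------

def _apply_mechanism(ds: RMDataset, config: ScenarioConfig,
                     rep_index: int) -> RMDataset:
    seed = _rng(config.seed, rep_index, 1)
    if config.missing_mechanism == "none":
        return ds
    if config.missing_mechanism == "mcar":
        return apply_mcar(ds, config.missing_rate, seed)
    pairs = config.mar_pairs or default_pairs(config.d)
    if config.missing_mechanism == "mar1":
        center, scale = _marginal_moments(config)
        return apply_mar1(ds, seed, pairs=pairs, center=center, scale=scale)
    return apply_mar2(ds, seed, pairs=pairs)


def _run_method(method: str, ds: RMDataset, C: ContrastSpec,
                quantile_seed: int) -> float:
    """p-value of one method on one dataset."""
    if method in ("wts", "ats1", "ats2"):
        eff = unweighted_effects(ds)
        V = covariance_psd(ds, eff)
        fn = {"wts": inference.wts, "ats1": inference.ats1, "ats2": inference.ats2}[method]
        return fn(eff.p_hat, V, C, ds.n_subjects).p_value
    if method == "mctp":
        return inference.mctp_global_pvalue(ds, C, approx="mvt", seed=quantile_seed)
    if method == "wts_F_domhof":
        return inference.wts_weighted(ds, C).p_value
    if method == "ats_F_domhof":
        return inference.ats_weighted(ds, C).p_value
    raise ValidationError(f"unknown method {method!r}")


def run_study(config: ScenarioConfig, methods: list[str] | None = None,
              handling: str = "all_available",
              contrast: ContrastSpec | None = None) -> StudyResult:
    """Monte-Carlo type-I error / power study for one scenario.

    Per replicate: generate a complete dataset, impose the missingness
    mechanism, apply the handling strategy and evaluate every requested
    method at level ``alpha``.  Replicates on which a method raises an
    estimation error (e.g. no complete case left) count as failures for
    that method and are excluded from its denominator.
    """
    methods = list(methods or ["ats2"])
    bad = [m for m in methods if m not in _METHODS]
    if bad:
        raise ValidationError(f"unknown method(s): {', '.join(bad)}")
    if handling not in _HANDLINGS:
        raise ValidationError(f"unknown handling {handling!r}")
    C = contrast or tukey_contrast(config.d)
    rejections = {m: 0 for m in methods}
    failures = {m: 0 for m in methods}
    completed = {m: 0 for m in methods}
    for rep in range(config.reps):
        qseed = int(_rng(config.seed, rep, 2).integers(0, 2**31 - 1))
        handled: RMDataset | None = None
        handle_error: Exception | None = None
        try:
            # a mechanism can empty an entire condition on unlucky draws,
            # which dataset validation rejects: count the rep as failed
            ds = _apply_mechanism(generate(config, rep), config, rep)
            if handling == "complete_case":
                handled = complete_cases(ds)
            elif handling == "median_impute":
                handled = median_impute(ds)
            else:
                handled = ds
        except (EstimationError, ValidationError) as exc:
            handle_error = exc
        for m in methods:
            if handle_error is not None:
                failures[m] += 1
                continue
            try:
                p = _run_method(m, handled, C, qseed)
            except (EstimationError, ValidationError, np.linalg.LinAlgError):
                failures[m] += 1
                continue
            completed[m] += 1
            rejections[m] += int(p <= config.alpha)
    return StudyResult(config=config, handling=handling, rejections=rejections,
                       failures=failures, reps_completed=completed)
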