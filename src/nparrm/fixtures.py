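"""Built-in example datasets.

Two fixtures are provided: a three-subject worked example whose relative
effects are known in closed form (used throughout the documentation and
tests), and a synthetic dataset shaped like an ordinal headache-severity
trial — 135 subjects scored 0-20 over four sessions with a realistic,
mostly monotone dropout pattern.  The severity dataset is synthetic: the
values are drawn from a correlated latent-normal model mapped to a skewed
0-20 integer scale, and only the shape (n, d, score range, missingness
pattern frequencies) emulates such a trial.
"""

from __future__ import annotations

import numpy as np

from .data_model import RMDataset

__all__ = ["worked_example", "WORKED_EXPECTED", "synthetic_severity_trial",
           "SEVERITY_PATTERNS"]

#: Certified effects of the worked example (exact rational values):
#: unweighted p_hat = (3/8, 5/8), weighted r_hat = (2/5, 13/20),
#: pairwise p(1,2) = 3/4.
WORKED_EXPECTED = {
    "p_hat": (0.375, 0.625),
    "r_hat": (0.4, 0.65),
    "pairwise_12": 0.75,
}

#: Missingness patterns (O = observed, M = missing) and subject counts of
#: the synthetic severity trial; mostly monotone dropout, two subjects
#: never observed, 33 complete cases out of 135.
SEVERITY_PATTERNS: list[tuple[str, int]] = [
    ("OOOO", 33),
    ("OOOM", 48),
    ("OOMM", 42),
    ("OMMM", 2),
    ("MOOO", 2),
    ("MMOO", 4),
    ("MMMO", 1),
    ("MMMM", 2),
    ("OMOO", 1),
]


def worked_example() -> RMDataset:
    """The d=2 worked example: rows (1, 2), (3, NA), (2, 4)."""
    values = np.array([[1.0, 2.0], [3.0, np.nan], [2.0, 4.0]])
    lam = np.array([[1, 1], [1, 0], [1, 1]])
    return RMDataset(values, lam)


def synthetic_severity_trial(seed: int = 0) -> RMDataset:
    """Synthetic four-session ordinal severity trial (n=135, scores 0-20).

    Latent scores follow a correlated multivariate normal with a mild
    improvement trend over sessions; they are mapped through an exponential
    transform to a right-skewed integer scale clipped to 0-20, emulating
    severity scores where most subjects sit low with a long upper tail.
    The missingness pattern frequencies are fixed (see
    :data:`SEVERITY_PATTERNS`); which subject receives which pattern is
    randomized by ``seed``.  Missingness is assigned independently of the
    values, i.e. the mechanism is completely at random given the pattern
    table.
    """
    rng = np.random.default_rng(seed)
    n, d = sum(c for _, c in SEVERITY_PATTERNS), 4
    rho = 0.7
    corr = rho ** np.abs(np.subtract.outer(np.arange(d), np.arange(d)))
    shift = np.array([0.25, -0.05, -0.25, 0.05])  # improves to session 3, rebounds
    z = rng.multivariate_normal(shift, corr, size=n, method="svd")
    scores = np.clip(np.rint(np.exp(1.25 + 0.85 * z)), 0, 20)

    patterns = [p for p, c in SEVERITY_PATTERNS for _ in range(c)]
    rng.shuffle(patterns)
    lam = np.array([[1 if ch == "O" else 0 for ch in pat] for pat in patterns])
    values = np.where(lam == 1, scores, np.nan)
    ids = [f"S{k + 1:03d}" for k in range(n)]
    return RMDataset(values, lam,
                     [f"session{i + 1}" for i in range(d)], ids)
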