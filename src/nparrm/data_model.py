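"""Data containers and contrast construction for repeated measures with missing values.

A dataset holds ``n`` subjects observed under ``d`` repeated conditions
(time points, sessions, treatments).  Missingness is carried explicitly in
an observation-indicator matrix ``lam`` with entries ``lam[k, i] = 1`` when
subject ``k`` was observed under condition ``i`` and ``0`` otherwise; the
value matrix stores NaN wherever the indicator is zero, so arithmetic can
never silently consume a missing cell.

Hypotheses about the vector of relative effects ``p`` are encoded by a
contrast matrix ``C`` whose rows sum to zero; the associated projection
``M = C' [C C']^+ C`` (Moore-Penrose inverse) defines the equivalent
hypothesis ``M p = 0`` used by the ANOVA-type statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "RMDataset",
    "ContrastSpec",
    "PopulationSpec",
    "read_wide",
    "write_wide",
    "tukey_contrast",
    "dunnett_contrast",
    "projection_matrix",
]

#: NA tokens recognised by default when reading delimited files.
DEFAULT_NA_TOKENS = ("", "NA")

_SV_RTOL = 1e-10  # relative singular-value cutoff for pseudoinverses / ranks


@dataclass
class RMDataset:
    """``n x d`` repeated-measures data with an explicit observation indicator.

    Parameters
    ----------
    values
        ``n x d`` float matrix; entries are NaN exactly where ``lam`` is 0.
    lam
        ``n x d`` matrix of 0/1 observation indicators.
    condition_names
        Optional labels for the ``d`` conditions (defaults to ``C1..Cd``).
    subject_ids
        Optional labels for the ``n`` subjects.
    """

    values: np.ndarray
    lam: np.ndarray
    condition_names: list[str] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lam = np.asarray(self.lam, dtype=int)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-d (subjects x conditions) array")
        if self.values.shape != self.lam.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != indicator shape {self.lam.shape}"
            )
        if not np.isin(self.lam, (0, 1)).all():
            raise ValidationError("observation indicators must be 0 or 1")
        obs = self.lam == 1
        if not np.isfinite(self.values[obs]).all():
            raise ValidationError("non-finite value in a cell marked as observed")
        # keep the invariant: unobserved cells are NaN, no sentinel values
        self.values = np.where(obs, self.values, np.nan)
        if not self.condition_names:
            self.condition_names = [f"C{i + 1}" for i in range(self.n_conditions)]
        if len(self.condition_names) != self.n_conditions:
            raise ValidationError("condition_names length does not match d")
        if self.subject_ids and len(self.subject_ids) != self.n_subjects:
            raise ValidationError("subject_ids length does not match n")
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]

    @property
    def lam_per_condition(self) -> np.ndarray:
        """Number of observed subjects per condition (d-vector)."""
        return self.lam.sum(axis=0)

    @property
    def n_total_obs(self) -> int:
        """Total number of observed cells N."""
        return int(self.lam.sum())

    def validate(self) -> None:
        """Require at least one observation in every condition."""
        lam_i = self.lam_per_condition
        if (lam_i == 0).any():
            bad = [self.condition_names[i] for i in np.nonzero(lam_i == 0)[0]]
            raise ValidationError(
                f"condition(s) without any observed value: {', '.join(bad)}"
            )

    def drop_all_missing_subjects(self) -> "RMDataset":
        """Return a copy without subjects that were never observed.

        By default fully missing subjects are retained: the model counts
        ``n`` i.i.d. subject vectors, and such subjects enter the sqrt(n)
        scaling and the ``n - 1`` covariance divisor with zero influence.
        """
        keep = self.lam.sum(axis=1) > 0
        ids = [s for s, k in zip(self.subject_ids, keep) if k] if self.subject_ids else []
        return RMDataset(self.values[keep], self.lam[keep],
                         list(self.condition_names), ids)

    def pattern_counts(self) -> dict[str, int]:
        """Missingness patterns ('O'=observed, 'M'=missing) with their counts."""
        out: dict[str, int] = {}
        for row in self.lam:
            key = "".join("O" if v else "M" for v in row)
            out[key] = out.get(key, 0) + 1
        return out

    def copy(self) -> "RMDataset":
        return RMDataset(self.values.copy(), self.lam.copy(),
                         list(self.condition_names), list(self.subject_ids))


@dataclass
class ContrastSpec:
    """A ``q x d`` contrast matrix with zero row sums and its projection matrix."""

    C: np.ndarray
    M: np.ndarray = field(default=None)  # type: ignore[assignment]
    row_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        rowsums = self.C.sum(axis=1)
        if np.abs(rowsums).max() > 1e-12:
            raise ValidationError("every contrast row must sum to 0")
        if self.M is None:
            self.M = projection_matrix(self.C)
        self.M = np.asarray(self.M, dtype=float)
        if not self.row_labels:
            self.row_labels = [f"c{i + 1}" for i in range(self.C.shape[0])]

    @property
    def q(self) -> int:
        return self.C.shape[0]

    @property
    def d(self) -> int:
        return self.C.shape[1]


@dataclass
class PopulationSpec:
    """Theoretical (population-level) quantities; a documentation container.

    Houses the symbols of the asymptotic theory so they have a typed home:
    the normalized marginal distributions ``F_i`` (average of the left- and
    right-continuous CDF versions), the weighted mean distribution ``H_N``
    and its unweighted counterpart ``G``, the weighted effects ``r_iN``, the
    unweighted relative effects ``p_i = ∫G dF_i``, the pairwise effects
    ``p(is) = ∫F_i dF_s``, the asymptotic covariance ``V_n`` of
    ``sqrt(n)(p_hat - p)`` and the influence variables behind it.  Nothing
    here is estimated; estimators live in :mod:`nparrm.effects` and
    :mod:`nparrm.covariance`, and these fields serve as oracles in tests.
    """

    marginals: object = None          # F_i, i = 1..d
    weighted_mean_dist: object = None  # H_N
    unweighted_mean_dist: object = None  # G
    weighted_effects: np.ndarray | None = None    # r_iN
    unweighted_effects: np.ndarray | None = None  # p_i
    pairwise_effects: np.ndarray | None = None    # p(is)
    asymptotic_covariance: np.ndarray | None = None  # V_n
    influence_variables: object = None  # Psi_ik, B_i


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def projection_matrix(C: np.ndarray) -> np.ndarray:
    """Projection ``M = C' [C C']^+ C`` onto the row space of ``C``.

    The generalized inverse is fixed to the Moore-Penrose pseudoinverse
    (singular values below ``1e-10`` times the largest treated as zero),
    which makes ``M`` unique, symmetric and idempotent.  The hypotheses
    ``C p = 0`` and ``M p = 0`` are equivalent.
    """
    C = np.atleast_2d(np.asarray(C, dtype=float))
    M = C.T @ np.linalg.pinv(C @ C.T, rcond=_SV_RTOL) @ C
    return (M + M.T) / 2.0


def tukey_contrast(d: int, names: list[str] | None = None) -> ContrastSpec:
    """All-pairwise (Tukey-type) contrasts for ``d`` conditions.

    Rows are ordered (1,2), (1,3), ..., (1,d), (2,3), ..., (d-1,d); the row
    for pair ``(i, j)`` carries ``-1`` at ``i`` and ``+1`` at ``j`` so the
    estimated contrast is ``p_j - p_i``.
    """
    if d < 2:
        raise ValidationError("Tukey contrasts need d >= 2")
    names = names or [f"C{i + 1}" for i in range(d)]
    rows, labels = [], []
    for i, j in itertools.combinations(range(d), 2):
        row = np.zeros(d)
        row[i], row[j] = -1.0, 1.0
        rows.append(row)
        labels.append(f"{names[j]} - {names[i]}")
    return ContrastSpec(np.array(rows), row_labels=labels)


def dunnett_contrast(d: int, control: int = 1,
                     names: list[str] | None = None) -> ContrastSpec:
    """Many-to-one (Dunnett-type) contrasts against condition ``control`` (1-based)."""
    if d < 2:
        raise ValidationError("Dunnett contrasts need d >= 2")
    if not 1 <= control <= d:
        raise ValidationError(f"control must be in 1..{d}, got {control}")
    names = names or [f"C{i + 1}" for i in range(d)]
    c0 = control - 1
    rows, labels = [], []
    for j in range(d):
        if j == c0:
            continue
        row = np.zeros(d)
        row[c0], row[j] = -1.0, 1.0
        rows.append(row)
        labels.append(f"{names[j]} - {names[c0]}")
    return ContrastSpec(np.array(rows), row_labels=labels)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_wide(path, condition_columns: list[str], *,
              subject_column: str | None = None,
              na_tokens: tuple[str, ...] = DEFAULT_NA_TOKENS,
              delimiter: str | None = None,
              drop_all_missing: bool = False) -> RMDataset:
    """Read a wide-format delimited table: one row per subject, one column per condition.

    Missing cells must be encoded by one of ``na_tokens`` (default: empty
    string or ``NA``).  The delimiter is autodetected from the file
    extension (``.tsv``/``.txt`` -> tab, otherwise comma) unless given.
    A non-numeric cell that is not an NA token raises a parse error naming
    the row and column; a condition column with no observed value at all
    raises a validation error.
    """
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith((".tsv", ".txt")) else ","
    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False,
                        skipinitialspace=True)
    missing_cols = [c for c in condition_columns if c not in frame.columns]
    if missing_cols:
        raise ValidationError(
            f"column(s) not found in {path}: {', '.join(missing_cols)}"
        )
    n, d = len(frame), len(condition_columns)
    values = np.full((n, d), np.nan)
    lam = np.zeros((n, d), dtype=int)
    na = set(na_tokens)
    for j, col in enumerate(condition_columns):
        for k, cell in enumerate(frame[col].astype(str).str.strip()):
            if cell in na:
                continue
            try:
                values[k, j] = float(cell)
            except ValueError as exc:
                raise ValidationError(
                    f"cannot parse {cell!r} in row {k + 1}, column {col!r} "
                    f"of {path}: not numeric and not an NA token"
                ) from exc
            lam[k, j] = 1
    ids = (frame[subject_column].astype(str).tolist()
           if subject_column and subject_column in frame.columns else [])
    ds = RMDataset(values, lam, list(condition_columns), ids)
    if drop_all_missing:
        ds = ds.drop_all_missing_subjects()
    return ds


def write_wide(ds: RMDataset, path, *, na_token: str = "NA",
               delimiter: str | None = None) -> None:
    """Write a dataset as a wide delimited table (inverse of :func:`read_wide`)."""
    path = str(path)
    if delimiter is None:
        delimiter = "\t" if path.endswith((".tsv", ".txt")) else ","
    cols = {}
    if ds.subject_ids:
        cols["subject"] = ds.subject_ids
    for j, name in enumerate(ds.condition_names):
        col = [
            (repr_num(ds.values[k, j]) if ds.lam[k, j] else na_token)
            for k in range(ds.n_subjects)
        ]
        cols[name] = col
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)


def repr_num(x: float) -> str:
    """Shortest faithful text form of a float (integers without trailing .0)."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))
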