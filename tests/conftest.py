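"""Shared fixtures and dataset builders for the test suite."""

import numpy as np
import pytest

from nparrm import RMDataset, worked_example


def random_missing_dataset(rng, n=None, d=None, integer=True,
                           missing_prob=0.25) -> RMDataset:
    """A small random dataset with missing cells and >= 1 observation per condition."""
    n = n or int(rng.integers(3, 9))
    d = d or int(rng.integers(2, 5))
    if integer:
        values = rng.integers(0, 6, size=(n, d)).astype(float)
    else:
        values = rng.normal(size=(n, d))
    lam = (rng.random((n, d)) >= missing_prob).astype(int)
    for i in range(d):  # guarantee estimability
        if lam[:, i].sum() == 0:
            lam[int(rng.integers(0, n)), i] = 1
    return RMDataset(np.where(lam == 1, values, np.nan), lam)


def complete_dataset(rng, n=10, d=3, integer=False) -> RMDataset:
    values = (rng.integers(0, 8, size=(n, d)).astype(float) if integer
              else rng.normal(size=(n, d)))
    return RMDataset(values, np.ones((n, d), dtype=int))


@pytest.fixture
def worked():
    """The d=2 worked example: rows (1,2), (3,NA), (2,4)."""
    return worked_example()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
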