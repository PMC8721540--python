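"""Exception hierarchy.

``ValidationError`` covers malformed inputs (bad files, bad contrast
matrices, conditions without any observation); ``EstimationError`` covers
datasets on which an estimator is undefined (too few observations, zero
complete cases); ``DegenerateTestError`` covers test statistics whose
reference distribution collapses (zero-rank covariance, zero trace).
"""


class NparrmError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NparrmError, ValueError):
    """Input data or configuration violates a structural requirement."""


class EstimationError(NparrmError, RuntimeError):
    """An estimator is not computable on the given dataset."""


class DegenerateTestError(EstimationError):
    """A test statistic's reference distribution is degenerate."""
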