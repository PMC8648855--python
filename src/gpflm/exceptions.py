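"""Exception hierarchy for gpflm.

All package-specific errors derive from :class:`GpflmError` so callers can
catch one base class; input-shaped problems additionally derive from
``ValueError`` for ergonomic use in scripts.
"""


class GpflmError(Exception):
    """Base class for all gpflm errors."""


class InvalidGridError(GpflmError, ValueError):
    """Grid is not strictly increasing, too short, or outside its domain."""


class InsufficientSampleError(GpflmError, ValueError):
    """Operation requires more subjects than were supplied."""


class NoVariationError(GpflmError, ValueError):
    """All eigenvalues are zero; truncation selection is undefined."""


class ShapeError(GpflmError, ValueError):
    """Mismatched array dimensions between related inputs."""


class InputError(GpflmError, ValueError):
    """Malformed user input (CSV contents, response coding, config)."""


class AlignmentError(InputError):
    """Subject identifiers do not line up across input files."""


class SingularDesignError(GpflmError, ValueError):
    """Weighted normal equations are singular; consider a small ridge."""


class DegenerateCovariateError(GpflmError, ValueError):
    """A scalar covariate carries no information (nu-hat is zero)."""


class SingularCovarianceError(GpflmError, ValueError):
    """Generalized covariance matrix has a (near-)zero eigenvalue."""


class UndefinedMetricError(GpflmError, ValueError):
    """A goodness-of-fit metric is undefined for these inputs."""


class NonConvergenceError(GpflmError, RuntimeError):
    """Raised by the CLI when a fit did not converge and that is fatal."""
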