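"""Package-specific exception types.

All inherit from :class:`VelquantError` so callers can catch the package's
failures with one clause while still distinguishing the specific cause.
"""


class VelquantError(Exception):
    """Base class for all velquant errors."""


class ROIError(VelquantError, ValueError):
    """Invalid region of interest: out of bounds, too small, or malformed."""


class DegenerateReferenceError(VelquantError, ValueError):
    """Reference region has zero/negative mean or zero spread; the
    normalization ratios are undefined."""


class NotPositiveDefiniteError(VelquantError, ValueError):
    """A covariance matrix required to be positive definite is not."""


class SingularCovarianceError(VelquantError, ValueError):
    """A fitted covariance matrix is singular and no ridge regularization
    was requested."""


class SchemaError(VelquantError, ValueError):
    """A feature table or manifest does not conform to the expected schema."""
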