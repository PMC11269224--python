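"""Exception hierarchy for saegbls.

All package errors derive from :class:`SaeGblsError`; the value-like ones
also derive from :class:`ValueError` so callers can catch either.
"""


class SaeGblsError(Exception):
    """Base class for all saegbls errors."""


class DimensionError(SaeGblsError, ValueError):
    """Array shapes do not conform (wrong column count, length mismatch)."""


class ParameterError(SaeGblsError, ValueError):
    """A scalar parameter is outside its admissible range."""


class ValidationError(SaeGblsError, ValueError):
    """A data structure violates its invariants."""


class FormatError(SaeGblsError):
    """A file could not be parsed in the requested format."""


class SingularSystemError(SaeGblsError):
    """A linear system to be solved is singular.

    Usually raised when the ridge penalty is zero and the design matrix is
    rank deficient; the fix is to use a strictly positive regularization
    weight.
    """
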