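"""Exception hierarchy used across the package."""


class CoupleMrError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CoupleMrError, ValueError):
    """An argument is outside its documented domain."""


class InfeasibleModelError(CoupleMrError):
    """The requested assortment/parental-effect targets imply a covariance
    matrix that is not positive semi-definite (no such population exists)."""


class NoInstrumentStrengthError(CoupleMrError):
    """All instrument-exposure effects are zero; the causal effect is
    unidentified."""


class CollinearityError(CoupleMrError):
    """The exposure-effect matrix in a multivariable MR fit is rank deficient."""


class DegenerateInputError(CoupleMrError, ValueError):
    """Input has no usable variation (constant vector, all-missing, ...)."""


class ScreenFailureError(CoupleMrError):
    """A trait failed the instrument/correlation screen and must be skipped."""


class SchemaError(CoupleMrError, ValueError):
    """A tabular input file is missing required columns or is malformed."""
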