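"""Exception hierarchy shared across modules."""


class ChromacalError(Exception):
    """Base class for data/model errors raised by this package."""


class SingularFitError(ChromacalError, ValueError):
    """Least-squares design matrix is rank deficient (e.g. collinear colors)."""


class ImageFormatError(ChromacalError, ValueError):
    """Unreadable or unsupported image input (CMYK, 16-bit, ...)."""


class EmptyInputError(ChromacalError, ValueError):
    """Input table has no rows (treated as a usage error by the CLI)."""


class JoinError(ChromacalError, ValueError):
    """Measured/reference tables could not be joined on sample id."""


class CalibrationRangeError(ChromacalError, ValueError):
    """Response cannot be inverted inside the calibrated range (the N/A case)."""


class AmbiguousCalibrationError(ChromacalError, ValueError):
    """Quadratic inversion found two roots inside the calibrated range."""
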