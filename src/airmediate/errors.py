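"""Exception types raised across the package."""


class AirmediateError(Exception):
    """Base class for package-specific errors."""


class DataFormatError(AirmediateError, ValueError):
    """Input file or column could not be parsed into the expected form."""


class InsufficientDataError(AirmediateError, ValueError):
    """Fewer complete rows than the analysis requires."""


class DegenerateColumnError(AirmediateError, ValueError):
    """A column has zero variance where variation is required."""


class SpecificationError(AirmediateError, ValueError):
    """Model structure and variable roles are inconsistent."""


class CollinearityError(AirmediateError, ValueError):
    """A design matrix is rank deficient or numerically so."""
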